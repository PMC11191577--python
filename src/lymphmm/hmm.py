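"""Hidden Markov model core: transition/observation matrices and likelihoods.

The hidden state is the joint involvement pattern of all modeled lymph node
levels. Dynamics are monotone (no healing): per time step a healthy level
``v`` becomes involved with probability

    p_v = 1 - (1 - b_v) * prod_{r in pa(v) involved} (1 - t_rv),

the noisy-OR combination of direct seeding from the tumor and spread from
involved parent levels. Within a single time step spread may cascade along
the drainage DAG — a parent that becomes involved in this step can already
seed its children in the same step — so ``pa(v)`` is evaluated in the
*destination* state. One step from the all-healthy state therefore
reproduces exactly the one-pass Bayesian-network prior that this model
generalizes.

Diagnosis of each level (MRI) is a noisy binary observation of its hidden
state with fixed sensitivity and specificity. The number of elapsed
progression steps at diagnosis is unobserved and carries a binomial prior
whose success parameter differs between early (T1-T2) and late (T3-T4)
primary-tumor stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .graph import LymphGraph, enumerate_states, state_bits

__all__ = [
    "ParameterVector",
    "ObservationModel",
    "TimeConfig",
    "TimePrior",
    "Diagnosis",
    "node_transition_prob",
    "build_transition_matrix",
    "build_observation_matrix",
    "matrix_to_frame",
    "binomial_time_prior",
    "state_distribution",
    "state_distribution_over_time",
    "marginal_state_distribution",
    "diagnosis_likelihood",
    "patient_likelihood",
    "cohort_log_likelihood",
]

STAGES = ("early", "late")

NEGATIVE, POSITIVE, UNKNOWN = 0, 1, None


def _check_stage(stage: str) -> str:
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    return stage


@dataclass(frozen=True)
class ParameterVector:
    """All learnable spread probabilities plus the late-stage time parameter.

    Attributes
    ----------
    b
        Base probabilities, one per level in graph order.
    t
        Transition probabilities, one per level arc in graph order.
    p_late
        Success parameter of the binomial time prior for late T-stage.
    """

    b: tuple[float, ...]
    t: tuple[float, ...]
    p_late: float

    def __init__(self, b, t, p_late):  # noqa: D107
        object.__setattr__(self, "b", tuple(float(x) for x in np.atleast_1d(b)))
        object.__setattr__(self, "t", tuple(float(x) for x in np.atleast_1d(t)))
        object.__setattr__(self, "p_late", float(p_late))
        for x in (*self.b, *self.t, self.p_late):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"parameter {x} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([*self.b, *self.t, self.p_late], dtype=float)

    @classmethod
    def from_array(cls, graph: LymphGraph, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        nb, nt = graph.n_levels, len(graph.level_arcs)
        if arr.shape != (nb + nt + 1,):
            raise ValueError(
                f"expected {nb + nt + 1} parameters, got shape {arr.shape}"
            )
        return cls(b=arr[:nb], t=arr[nb : nb + nt], p_late=arr[-1])

    @staticmethod
    def names(graph: LymphGraph) -> list[str]:
        return graph.parameter_names + ["p_late"]

    def base(self, graph: LymphGraph, level: str) -> float:
        return self.b[graph.level_index(level)]

    def spread(self, graph: LymphGraph, source: str, target: str) -> float:
        for j, (r, s, _) in enumerate(graph.level_arcs):
            if (r, s) == (source, target):
                return self.t[j]
        raise KeyError(f"no arc {source}->{target}")


@dataclass(frozen=True)
class ObservationModel:
    """Per-level diagnostic accuracy of the imaging modality.

    ``sensitivity`` is the probability that a truly involved level is read
    positive, ``specificity`` that a truly healthy level is read negative.
    Defaults are the MRI values for head-and-neck nodal staging used
    throughout: sensitivity 0.81, specificity 0.63.
    """

    sensitivity: float = 0.81
    specificity: float = 0.63

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class TimeConfig:
    """Time-prior configuration: number of steps and the fixed early parameter.

    ``t_max`` steps of progression may elapse before diagnosis; the early
    (T1-T2) binomial success parameter ``p_early`` is fixed to anchor the
    model's time scale, while the late (T3-T4) parameter is learned as part
    of the ParameterVector.
    """

    t_max: int = 10
    p_early: float = 0.3

    def __post_init__(self) -> None:
        if int(self.t_max) != self.t_max or self.t_max < 1:
            raise ValueError(f"t_max must be an integer >= 1, got {self.t_max}")
        if not 0.0 <= self.p_early <= 1.0:
            raise ValueError(f"p_early must be in [0, 1], got {self.p_early}")


@dataclass(frozen=True)
class TimePrior:
    """Distribution over the number of elapsed progression steps 0..t_max."""

    t_max: int
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.t_max + 1,):
            raise ValueError("need one weight per time step 0..t_max")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("time-prior weights must be a distribution")


def binomial_time_prior(t_max: int, p: float) -> TimePrior:
    """Binomial(t_max, p) prior over the elapsed number of time steps."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    w = stats.binom.pmf(np.arange(t_max + 1), t_max, p)
    w = w / w.sum()
    return TimePrior(t_max=int(t_max), weights=tuple(w))


@dataclass(frozen=True)
class Diagnosis:
    """Observed per-level imaging status: 0 negative, 1 positive, None unknown."""

    statuses: tuple[int | None, ...]

    def __init__(self, statuses):  # noqa: D107
        clean = []
        for s in statuses:
            if s is None or (isinstance(s, float) and np.isnan(s)):
                clean.append(None)
            elif int(s) in (0, 1):
                clean.append(int(s))
            else:
                raise ValueError(f"diagnosis status must be 0, 1 or unknown, got {s!r}")
        object.__setattr__(self, "statuses", tuple(clean))

    @classmethod
    def from_dict(cls, graph: LymphGraph, mapping: dict) -> "Diagnosis":
        return cls(tuple(mapping.get(v, None) for v in graph.levels))

    @classmethod
    def all_negative(cls, graph: LymphGraph) -> "Diagnosis":
        return cls((0,) * graph.n_levels)

    def validate(self, graph: LymphGraph) -> "Diagnosis":
        if len(self.statuses) != graph.n_levels:
            raise ValueError(
                f"diagnosis has {len(self.statuses)} levels, graph has {graph.n_levels}"
            )
        return self

    def label(self, graph: LymphGraph) -> str:
        sym = {0: "-", 1: "+", None: "?"}
        return ",".join(f"{v}{sym[s]}" for v, s in zip(graph.levels, self.statuses))


# ---------------------------------------------------------------------------
# transition kernel
# ---------------------------------------------------------------------------


def node_transition_prob(
    level: str,
    state,
    theta: ParameterVector,
    graph: LymphGraph,
) -> float:
    """One-step involvement probability of a healthy level.

    Noisy-OR of the tumor arc and the arcs from parents involved in
    ``state``: ``1 - (1 - b_v) * prod (1 - t_rv)``.
    """
    bits = state.bits if hasattr(state, "bits") else tuple(state)
    if bits[graph.level_index(level)] == 1:
        raise ValueError(
            f"level {level} already involved; involved levels persist with probability 1"
        )
    stay_healthy = 1.0 - theta.base(graph, level)
    for parent, _ in graph.parents(level):
        if bits[graph.level_index(parent)] == 1:
            stay_healthy *= 1.0 - theta.spread(graph, parent, level)
    return 1.0 - stay_healthy


def _arc_indices(graph: LymphGraph) -> list[tuple[int, int]]:
    return [
        (graph.level_index(r), graph.level_index(s)) for r, s, _ in graph.level_arcs
    ]


def _transition_matrix_raw(
    S: np.ndarray, arc_idx: list[tuple[int, int]], b: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Kernel build from raw arrays; no parameter validation (hot path)."""
    stay = np.tile(1.0 - b, (S.shape[0], 1))
    for j, (ri, si) in enumerate(arc_idx):
        stay[:, si] *= np.where(S[:, ri] == 1, 1.0 - t[j], 1.0)
    P = 1.0 - stay  # p_v(y), indexed by destination state
    Sy = S[None, :, :]
    healthy = np.where(Sy == 1, P[None, :, :], stay[None, :, :])
    factors = np.where(S[:, None, :] == 1, Sy.astype(float), healthy)
    return factors.prod(axis=2)


def build_transition_matrix(graph: LymphGraph, theta: ParameterVector) -> np.ndarray:
    """``2**V x 2**V`` one-step state-transition kernel.

    Entry (x, y) is the product over levels of the per-level step
    probability: involved levels persist (factor ``y_v``); a healthy level
    becomes involved with probability ``p_v`` evaluated in the destination
    state ``y`` (within-step cascade along the DAG), else stays healthy with
    ``1 - p_v``. Rows are stochastic; entries with ``y`` not a progression
    of ``x`` are exactly zero; the all-involved state is absorbing.
    """
    return _transition_matrix_raw(
        state_bits(graph),
        _arc_indices(graph),
        np.asarray(theta.b),
        np.asarray(theta.t),
    )


def matrix_to_frame(matrix: np.ndarray, graph: LymphGraph):
    """Label a ``2**V x 2**V`` state matrix with bit-pattern headers.

    Row/column labels are involvement patterns in level order (e.g.
    ``'0101'``), ready for CSV export of transition or observation
    matrices.
    """
    import pandas as pd

    labels = ["".join(str(b) for b in s.bits) for s in enumerate_states(graph)]
    return pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)


def build_observation_matrix(obs: ObservationModel, graph: LymphGraph) -> np.ndarray:
    """``2**V x 2**V`` matrix of P(full diagnosis pattern z | hidden state x).

    Per-level factors: sensitivity (or its complement) where the level is
    truly involved, specificity (or its complement) where healthy. Rows sum
    to one; with perfect sensitivity and specificity this is the identity.
    """
    S = state_bits(graph)
    Sx = S[:, None, :]
    Sz = S[None, :, :]
    pos = np.where(Sx == 1, obs.sensitivity, 1.0 - obs.specificity)
    factors = np.where(Sz == 1, pos, 1.0 - pos)
    return factors.prod(axis=2)


# ---------------------------------------------------------------------------
# evolving the hidden-state distribution
# ---------------------------------------------------------------------------


def state_distribution(
    theta: ParameterVector, t: int, graph: LymphGraph
) -> np.ndarray:
    """Hidden-state distribution after ``t`` steps from the all-healthy state."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return state_distribution_over_time(theta, t, graph)[t]

def state_distribution_over_time(
    theta: ParameterVector, t_max: int, graph: LymphGraph
) -> np.ndarray:
    """``(t_max+1, 2**V)`` matrix of state distributions at t = 0..t_max."""
    A = build_transition_matrix(graph, theta)
    out = np.zeros((t_max + 1, graph.n_states))
    out[0, 0] = 1.0  # diagnosis time 0: tumor present, all levels healthy
    for t in range(1, t_max + 1):
        out[t] = out[t - 1] @ A
    return out


def _time_prior_for_stage(
    theta: ParameterVector, stage: str, time_config: TimeConfig
) -> TimePrior:
    p = time_config.p_early if _check_stage(stage) == "early" else theta.p_late
    return binomial_time_prior(time_config.t_max, p)


def marginal_state_distribution(
    theta: ParameterVector,
    stage: str,
    graph: LymphGraph,
    time_config: TimeConfig,
    time_prior: TimePrior | None = None,
) -> np.ndarray:
    """State distribution with the unknown diagnosis time marginalized out.

    Weighted sum over t of the t-step distribution, weights from the
    stage-appropriate binomial time prior (early uses the fixed
    ``p_early``; late uses the learned ``theta.p_late``). A custom
    ``time_prior`` overrides the binomial.
    """
    prior = time_prior or _time_prior_for_stage(theta, stage, time_config)
    dists = state_distribution_over_time(theta, prior.t_max, graph)
    return np.asarray(prior.weights) @ dists


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def diagnosis_likelihood(
    diagnosis: Diagnosis, obs: ObservationModel, graph: LymphGraph
) -> np.ndarray:
    """Vector over hidden states of P(observed diagnosis | state).

    Unknown levels contribute a factor of 1 (marginalized out).
    """
    diagnosis.validate(graph)
    S = state_bits(graph)
    like = np.ones(graph.n_states)
    for i, status in enumerate(diagnosis.statuses):
        if status is None:
            continue
        involved = S[:, i] == 1
        if status == 1:
            like *= np.where(involved, obs.sensitivity, 1.0 - obs.specificity)
        else:
            like *= np.where(involved, 1.0 - obs.sensitivity, obs.specificity)
    return like


def patient_likelihood(
    theta: ParameterVector,
    diagnosis: Diagnosis,
    stage: str,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    time_prior: TimePrior | None = None,
) -> float:
    """Marginal probability of one patient's diagnosis given parameters."""
    marg = marginal_state_distribution(theta, stage, graph, time_config, time_prior)
    return float(marg @ diagnosis_likelihood(diagnosis, obs, graph))


def cohort_log_likelihood(
    theta: ParameterVector,
    cohort,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
) -> float:
    """Sum of log patient likelihoods; -inf if any patient has likelihood 0.

    ``cohort`` is a :class:`lymphmm.synthetic.CohortTable` (or any iterable
    of records with ``stage_class`` and ``diagnosis(graph)``). The empty
    cohort has log-likelihood 0. Probability arithmetic stays in linear
    space per patient; only the cohort sum is taken in logs.
    """
    marg = {}
    total = 0.0
    for rec in cohort:
        stage = rec.stage_class
        if stage not in marg:
            marg[stage] = marginal_state_distribution(theta, stage, graph, time_config)
        lik = float(marg[stage] @ diagnosis_likelihood(rec.diagnosis(graph), obs, graph))
        if lik <= 0.0:
            return -np.inf
        total += np.log(lik)
    return total
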