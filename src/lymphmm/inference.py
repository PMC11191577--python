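"""Posterior inference over spread parameters via ensemble MCMC.

The posterior combines a uniform prior on the unit hypercube with the
cohort likelihood. Sampling uses the affine-invariant ensemble sampler
(emcee); the likelihood is precompiled so its cost is independent of cohort
size: patients are grouped by (stage, diagnosis pattern), each group
contributing count * log(P(pattern | stage, theta)).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import emcee
import numpy as np
import pandas as pd

from .graph import LymphGraph
from .hmm import (
    ObservationModel,
    ParameterVector,
    TimeConfig,
    diagnosis_likelihood,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "log_prior",
    "CohortLogPosterior",
    "sample_posterior",
    "summarize_posterior",
    "parameter_correlations",
    "write_posterior",
    "read_posterior",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``walkers=None`` means 10x the parameter count. Burn-in steps are
    discarded, ``steps`` are retained, thinned by ``thin``.
    """

    walkers: int | None = None
    steps: int = 10_000
    burn_in: int = 2_000
    thin: int = 1

    def __post_init__(self) -> None:
        for name in ("steps", "burn_in", "thin"):
            v = getattr(self, name)
            if int(v) != v or v < (1 if name != "burn_in" else 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def n_walkers(self, ndim: int) -> int:
        n = self.walkers if self.walkers is not None else 10 * ndim
        if n < 2 * ndim + 2:
            raise ValueError(
                f"{n} walkers insufficient for {ndim} parameters "
                f"(need at least {2 * ndim + 2})"
            )
        return int(n)


@dataclass
class PosteriorSamples:
    """Flattened MCMC draws of the ParameterVector with chain metadata."""

    draws: np.ndarray  # (n_samples, n_parameters)
    parameter_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[0] < 1:
            raise ValueError("draws must be a non-empty (n_samples, d) matrix")
        if self.draws.shape[1] != len(self.parameter_names):
            raise ValueError("parameter_names do not match draw dimension")
        if np.any(self.draws < 0) or np.any(self.draws > 1):
            raise ValueError("posterior draws must lie in [0, 1]^d")

    def __len__(self) -> int:
        return self.draws.shape[0]

    def parameter_vectors(self, graph: LymphGraph):
        """Iterate draws as ParameterVector objects."""
        for row in self.draws:
            yield ParameterVector.from_array(graph, row)

    def mean_parameters(self, graph: LymphGraph) -> ParameterVector:
        return ParameterVector.from_array(graph, self.draws.mean(axis=0))


def log_prior(theta_array: np.ndarray) -> float:
    """Uniform prior on the closed unit hypercube: 0 inside, -inf outside."""
    theta_array = np.asarray(theta_array, dtype=float)
    if np.all((theta_array >= 0.0) & (theta_array <= 1.0)):
        return 0.0
    return -np.inf


class CohortLogPosterior:
    """Callable log-posterior with the cohort compiled to pattern counts.

    Grouping patients by (stage, diagnosis pattern) makes each evaluation
    O(t_max * 4^V) regardless of cohort size.
    """

    def __init__(
        self,
        cohort,
        graph: LymphGraph,
        obs: ObservationModel,
        time_config: TimeConfig,
    ) -> None:
        from scipy.special import comb

        from .graph import state_bits
        from .hmm import _arc_indices

        self.graph = graph
        self.time_config = time_config
        self.ndim = graph.n_levels + len(graph.level_arcs) + 1
        self._S = state_bits(graph)
        self._arc_idx = _arc_indices(graph)
        self._comb = comb(time_config.t_max, np.arange(time_config.t_max + 1))
        self._trange = np.arange(time_config.t_max + 1)
        groups: dict[str, dict[tuple, int]] = {"early": {}, "late": {}}
        n = 0
        for rec in cohort:
            key = tuple(rec.diagnosis(graph).statuses)
            groups[rec.stage_class][key] = groups[rec.stage_class].get(key, 0) + 1
            n += 1
        if n == 0:
            raise ValueError("empty cohort")
        self.n_patients = n
        self._stage_blocks = []
        for stage, patterns in groups.items():
            if not patterns:
                continue
            from .hmm import Diagnosis

            D = np.stack(
                [
                    diagnosis_likelihood(Diagnosis(p), obs, graph)
                    for p in patterns
                ]
            )
            counts = np.array(list(patterns.values()), dtype=float)
            self._stage_blocks.append((stage, D, counts))

    def _binom_weights(self, p: float) -> np.ndarray:
        t_max, k = self.time_config.t_max, self._trange
        with np.errstate(invalid="ignore"):
            w = self._comb * p**k * (1.0 - p) ** (t_max - k)
        w[np.isnan(w)] = 0.0  # 0**0 corner at p in {0, 1}
        return w / w.sum()

    def log_likelihood(self, theta_array: np.ndarray) -> float:
        theta_array = np.asarray(theta_array, dtype=float)
        nb = self.graph.n_levels
        nt = len(self.graph.level_arcs)
        b, t, p_late = theta_array[:nb], theta_array[nb : nb + nt], theta_array[-1]
        from .hmm import _transition_matrix_raw

        A = _transition_matrix_raw(self._S, self._arc_idx, b, t)
        t_max = self.time_config.t_max
        dists = np.zeros((t_max + 1, self.graph.n_states))
        dists[0, 0] = 1.0
        for i in range(1, t_max + 1):
            dists[i] = dists[i - 1] @ A
        total = 0.0
        for stage, D, counts in self._stage_blocks:
            p = self.time_config.p_early if stage == "early" else p_late
            marg = self._binom_weights(p) @ dists
            probs = D @ marg
            if np.any(probs <= 0.0):
                return -np.inf
            total += counts @ np.log(probs)
        return float(total)

    def __call__(self, theta_array: np.ndarray) -> float:
        lp = log_prior(theta_array)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(theta_array)


def sample_posterior(
    cohort,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    seed: int,
    sampler_config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Draw posterior samples of the ParameterVector given a cohort.

    Deterministic given ``seed``. Walkers start uniform in [0.1, 0.9]^d;
    burn-in is discarded. Acceptance fraction and the integrated
    autocorrelation time estimate are reported in ``meta``; a warning is
    logged if the retained chain is shorter than 50x the autocorrelation
    time.
    """
    cfg = sampler_config or SamplerConfig()
    logpost = CohortLogPosterior(cohort, graph, obs, time_config)
    ndim = logpost.ndim
    nwalkers = cfg.n_walkers(ndim)
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, size=(nwalkers, ndim))
    finite = np.array([np.isfinite(logpost(p)) for p in p0])
    if not finite.all():
        bad = int((~finite).sum())
        raise RuntimeError(
            f"{bad}/{nwalkers} walker initializations have zero posterior "
            "probability; the cohort contains patterns impossible under the model"
        )
    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31))
    ).get_state()
    logger.info(
        "MCMC: %d walkers, %d+%d steps, %d patients grouped into %d pattern blocks",
        nwalkers, cfg.burn_in, cfg.steps, logpost.n_patients,
        sum(len(c) for _, _, c in logpost._stage_blocks),
    )
    sampler.run_mcmc(p0, cfg.burn_in + cfg.steps, progress=False)
    draws = sampler.get_chain(discard=cfg.burn_in, thin=cfg.thin, flat=True)
    acceptance = float(np.mean(sampler.acceptance_fraction))
    try:
        tau = sampler.get_autocorr_time(discard=cfg.burn_in, tol=0)
        tau_max = float(np.nanmax(tau))
    except Exception:  # pragma: no cover - emcee raises on pathological chains
        tau, tau_max = None, float("nan")
    if np.isfinite(tau_max) and cfg.steps < 50 * tau_max:
        logger.warning(
            "retained chain (%d steps) shorter than 50x the autocorrelation "
            "time estimate (%.1f); consider more steps", cfg.steps, tau_max,
        )
    meta = {
        "seed": int(seed),
        "n_walkers": nwalkers,
        "burn_in": cfg.burn_in,
        "steps": cfg.steps,
        "thin": cfg.thin,
        "acceptance_fraction": acceptance,
        "autocorr_time": None if tau is None else [float(x) for x in tau],
        "n_patients": logpost.n_patients,
    }
    return PosteriorSamples(
        draws=draws, parameter_names=ParameterVector.names(graph), meta=meta
    )


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter mean, standard deviation and 16th/84th percentiles."""
    if len(samples) < 2:
        raise ValueError("need at least 2 draws to summarize")
    d = samples.draws
    return pd.DataFrame(
        {
            "mean": d.mean(axis=0),
            "sd": d.std(axis=0, ddof=1),
            "p16": np.percentile(d, 16, axis=0),
            "p84": np.percentile(d, 84, axis=0),
        },
        index=pd.Index(samples.parameter_names, name="parameter"),
    )


def parameter_correlations(samples: PosteriorSamples) -> pd.DataFrame:
    """Pairwise Pearson correlations; zero-variance parameters yield NaN."""
    if len(samples) < 3:
        raise ValueError("need at least 3 draws for correlations")
    d = samples.draws
    sd = d.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(d, rowvar=False)
    corr = np.atleast_2d(corr)
    degenerate = sd <= 1e-12  # numerically constant columns
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    names = samples.parameter_names
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_posterior(samples: PosteriorSamples, path) -> None:
    """One CSV row per draw, one column per parameter; meta in # comments."""
    buf = io.StringIO()
    buf.write("# meta: " + json.dumps(samples.meta, sort_keys=True) + "\n")
    pd.DataFrame(samples.draws, columns=samples.parameter_names).to_csv(
        buf, index=False
    )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_posterior(path) -> PosteriorSamples:
    text = Path(path).read_text(encoding="utf-8")
    meta: dict = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("# ").strip()
        if body.startswith("meta:"):
            meta = json.loads(body[len("meta:"):])
    frame = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    return PosteriorSamples(
        draws=frame.to_numpy(dtype=float),
        parameter_names=list(frame.columns),
        meta=meta,
    )
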