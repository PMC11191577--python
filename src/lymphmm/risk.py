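"""Risk of occult (microscopic) involvement given an observed diagnosis.

Bayes rule over hidden states: the stage-specific time-marginalized state
distribution is the prior, the sensitivity/specificity observation model
the likelihood of the observed MRI pattern. The risk of a level (or of a
set of levels jointly) is the posterior mass on states where it is
involved. The one-pass Bayesian-network model that this HMM generalizes is
provided as a closed form for comparison; with a point-mass time prior at
one step the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import LymphGraph, state_bits
from .hmm import (
    Diagnosis,
    ObservationModel,
    ParameterVector,
    TimeConfig,
    TimePrior,
    diagnosis_likelihood,
    marginal_state_distribution,
)
from .inference import PosteriorSamples

__all__ = [
    "RiskQuery",
    "RiskTable",
    "state_posterior",
    "microscopic_risk",
    "bn_state_prior",
    "bn_risk",
    "risk_table",
    "standard_risk_queries",
]


class UndefinedPosteriorError(ValueError):
    """The conditioning diagnosis has probability zero under the model."""


def state_posterior(
    theta: ParameterVector,
    diagnosis: Diagnosis,
    stage: str,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    time_prior: TimePrior | None = None,
) -> np.ndarray:
    """P(hidden state | observed diagnosis, stage); sums to one."""
    prior = marginal_state_distribution(theta, stage, graph, time_config, time_prior)
    like = diagnosis_likelihood(diagnosis, obs, graph)
    joint = prior * like
    norm = joint.sum()
    if norm <= 0.0:
        raise UndefinedPosteriorError(
            f"diagnosis {diagnosis.label(graph)} has zero probability under theta"
        )
    return joint / norm


def _involvement_mask(graph: LymphGraph, levels) -> np.ndarray:
    if isinstance(levels, str):
        levels = (levels,)
    S = state_bits(graph)
    mask = np.ones(graph.n_states, dtype=bool)
    for v in levels:
        mask &= S[:, graph.level_index(v)] == 1
    return mask


def microscopic_risk(
    theta: ParameterVector,
    levels,
    diagnosis: Diagnosis,
    stage: str,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    time_prior: TimePrior | None = None,
) -> float:
    """Posterior probability that ``levels`` (one label or a set, jointly)
    are truly involved given the observed diagnosis."""
    post = state_posterior(theta, diagnosis, stage, graph, obs, time_config, time_prior)
    return float(post[_involvement_mask(graph, levels)].sum())


# ---------------------------------------------------------------------------
# one-pass Bayesian-network comparison model
# ---------------------------------------------------------------------------


def bn_state_prior(theta: ParameterVector, graph: LymphGraph) -> np.ndarray:
    """Hidden-state prior of the single-pass Bayesian network.

    P(x) = prod over levels in topological order of p_v or 1-p_v, with
    p_v = 1 - (1 - b_v) * prod over parents involved in x of (1 - t_rv).
    No time prior is involved; ``theta.p_late`` is ignored.
    """
    topo = graph.topological_levels()
    prior = np.zeros(graph.n_states)
    for idx in range(graph.n_states):
        bits = [(idx >> i) & 1 for i in range(graph.n_levels)]
        p = 1.0
        for v in topo:
            i = graph.level_index(v)
            stay = 1.0 - theta.base(graph, v)
            for parent, _ in graph.parents(v):
                if bits[graph.level_index(parent)] == 1:
                    stay *= 1.0 - theta.spread(graph, parent, v)
            p_v = 1.0 - stay
            p *= p_v if bits[i] == 1 else 1.0 - p_v
        prior[idx] = p
    return prior


def bn_risk(
    theta: ParameterVector,
    levels,
    diagnosis: Diagnosis,
    graph: LymphGraph,
    obs: ObservationModel,
) -> float:
    """Risk of involvement under the Bayesian-network model.

    Same Bayes conditioning as :func:`microscopic_risk` but with the
    one-pass BN state prior in place of the time-marginalized HMM prior.
    """
    prior = bn_state_prior(theta, graph)
    like = diagnosis_likelihood(diagnosis, obs, graph)
    joint = prior * like
    norm = joint.sum()
    if norm <= 0.0:
        raise UndefinedPosteriorError(
            f"diagnosis {diagnosis.label(graph)} has zero probability under theta"
        )
    return float(joint[_involvement_mask(graph, levels)].sum() / norm)


# ---------------------------------------------------------------------------
# posterior-sample risk tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskQuery:
    """One cell request: target level(s), conditioning diagnosis, stage."""

    levels: tuple[str, ...]
    diagnosis: Diagnosis
    stage: str
    label: str = ""

    def __init__(self, levels, diagnosis, stage, label=""):  # noqa: D107
        if isinstance(levels, str):
            levels = (levels,)
        object.__setattr__(self, "levels", tuple(levels))
        object.__setattr__(self, "diagnosis", diagnosis)
        object.__setattr__(self, "stage", stage)
        object.__setattr__(self, "label", label or "+".join(levels))


@dataclass
class RiskTable:
    """Per-query risk histograms over posterior draws plus summaries."""

    queries: list[RiskQuery]
    histograms: list[np.ndarray]  # one array of per-draw risks per query
    summary: pd.DataFrame  # rows align with queries

    def risks(self, i: int) -> np.ndarray:
        return self.histograms[i]


def risk_table(
    samples: PosteriorSamples,
    queries,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    max_draws: int = 2000,
    subsample_seed: int = 0,
) -> RiskTable:
    """Evaluate each query's risk at (a seeded subsample of) every draw.

    Summaries are the posterior mean, sd and 16/84 percentiles of the
    per-draw risks; percent columns mirror the two-decimal reporting style
    of clinical risk tables.
    """
    queries = list(queries)
    draws = samples.draws
    if max_draws is not None and len(draws) > max_draws:
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(len(draws), size=max_draws, replace=False)
        idx.sort()
        draws = draws[idx]
    thetas = [ParameterVector.from_array(graph, row) for row in draws]
    histograms = []
    rows = []
    for q in queries:
        risks = np.array(
            [
                microscopic_risk(
                    th, q.levels, q.diagnosis, q.stage, graph, obs, time_config
                )
                for th in thetas
            ]
        )
        histograms.append(risks)
        rows.append(
            {
                "levels": "+".join(q.levels),
                "diagnosis": q.diagnosis.label(graph),
                "stage": q.stage,
                "label": q.label,
                "mean": risks.mean(),
                "sd": risks.std(ddof=1) if len(risks) > 1 else 0.0,
                "p16": np.percentile(risks, 16),
                "p84": np.percentile(risks, 84),
                "mean_pct": round(100.0 * risks.mean(), 2),
            }
        )
    return RiskTable(queries=queries, histograms=histograms, summary=pd.DataFrame(rows))


def standard_risk_queries(graph: LymphGraph, stage: str = "early") -> list[RiskQuery]:
    """The canonical conditioning grid: N0, II only, II and III, III only.

    Each pattern is a full diagnosis vector with unlisted levels observed
    negative; every level of the graph is queried against every pattern.
    """
    patterns = {
        "N0": (),
        "II only": ("II",),
        "II and III": ("II", "III"),
        "III only": ("III",),
    }
    queries = []
    for name, positives in patterns.items():
        diag = Diagnosis(tuple(1 if v in positives else 0 for v in graph.levels))
        for v in graph.levels:
            queries.append(
                RiskQuery(levels=v, diagnosis=diag, stage=stage, label=f"{v} | {name}")
            )
    return queries
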