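"""Model evaluation: threefold cross-validation, calibration, BN comparison.

Cross-validation splits the cohort into three near-equal folds (stratified
by stage class so each fold preserves the early/late mix), trains on each
pair of folds and evaluates the held-out third, and also fits the full
cohort. Calibration compares the model-predicted probability of observable
diagnosis patterns, per posterior draw, against the beta distribution the
pattern's cohort prevalence implies under a uniform prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import LymphGraph, state_bits
from .hmm import (
    Diagnosis,
    ObservationModel,
    ParameterVector,
    TimeConfig,
    build_observation_matrix,
    cohort_log_likelihood,
    marginal_state_distribution,
)
from .inference import (
    PosteriorSamples,
    SamplerConfig,
    sample_posterior,
    summarize_posterior,
)
from .risk import bn_risk, microscopic_risk
from .synthetic import CohortTable

__all__ = [
    "CVReport",
    "assign_folds",
    "threefold_cv",
    "prevalence_beta",
    "predicted_vs_prevalence",
    "compare_bn_hmm",
]

logger = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Everything the threefold cross-validation produces."""

    fold_assignments: np.ndarray  # fold index per patient
    fold_summaries: list[pd.DataFrame]
    heldout_log_likelihood: list[float]
    heldout_log_likelihood_per_patient: list[float]
    train_log_likelihood_per_patient: list[float]
    full_summary: pd.DataFrame
    full_log_likelihood: float
    meta: dict = field(default_factory=dict)

    @property
    def fold_sizes(self) -> list[int]:
        return [int((self.fold_assignments == k).sum()) for k in range(3)]


def assign_folds(cohort: CohortTable, seed: int, n_folds: int = 3) -> np.ndarray:
    """Seeded fold assignment, stratified by stage class.

    Patients are shuffled within each stage class and dealt to the fold
    with the fewest members, so fold sizes differ by at most one overall
    and each fold preserves the early/late mix.
    """
    rng = np.random.default_rng(seed)
    assignment = np.full(len(cohort), -1, dtype=int)
    counts = np.zeros(n_folds, dtype=int)
    for stage in ("early", "late"):
        idx = [i for i, r in enumerate(cohort.records) if r.stage_class == stage]
        rng.shuffle(idx)
        for i in idx:
            k = int(np.argmin(counts))  # ties break to the lowest fold index
            assignment[i] = k
            counts[k] += 1
    return assignment


def threefold_cv(
    cohort: CohortTable,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    seed: int,
    sampler_config: SamplerConfig | None = None,
) -> CVReport:
    """Train on every pair of folds, score the held-out third, fit the whole.

    Held-out and training log-likelihoods are evaluated at the posterior
    mean of each training fit; the whole-dataset log-likelihood at the
    posterior mean of the full-cohort fit.
    """
    if len(cohort) < 3:
        raise ValueError("cross-validation needs at least 3 patients")
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(2**31, size=4)
    assignment = assign_folds(cohort, seed=int(rng.integers(2**31)))
    if any((assignment == k).sum() == 0 for k in range(3)):
        raise ValueError("a fold received zero patients")
    fold_summaries = []
    heldout_ll, heldout_pp, train_pp = [], [], []
    for k in range(3):
        train_idx = np.flatnonzero(assignment != k)
        test_idx = np.flatnonzero(assignment == k)
        train = cohort.subset(train_idx)
        test = cohort.subset(test_idx)
        samples = sample_posterior(
            train, graph, obs, time_config, seed=int(subseeds[k]),
            sampler_config=sampler_config,
        )
        theta_hat = samples.mean_parameters(graph)
        fold_summaries.append(summarize_posterior(samples))
        ll_test = cohort_log_likelihood(theta_hat, test, graph, obs, time_config)
        ll_train = cohort_log_likelihood(theta_hat, train, graph, obs, time_config)
        heldout_ll.append(float(ll_test))
        heldout_pp.append(float(ll_test) / len(test))
        train_pp.append(float(ll_train) / len(train))
        logger.info(
            "fold %d: train n=%d, heldout n=%d, heldout loglik %.2f",
            k, len(train), len(test), ll_test,
        )
    full_samples = sample_posterior(
        cohort, graph, obs, time_config, seed=int(subseeds[3]),
        sampler_config=sampler_config,
    )
    theta_full = full_samples.mean_parameters(graph)
    full_ll = float(
        cohort_log_likelihood(theta_full, cohort, graph, obs, time_config)
    )
    return CVReport(
        fold_assignments=assignment,
        fold_summaries=fold_summaries,
        heldout_log_likelihood=heldout_ll,
        heldout_log_likelihood_per_patient=heldout_pp,
        train_log_likelihood_per_patient=train_pp,
        full_summary=summarize_posterior(full_samples),
        full_log_likelihood=full_ll,
        meta={"seed": int(seed), "n_patients": len(cohort)},
    )


def prevalence_beta(k: int, n: int) -> tuple[float, float]:
    """Beta posterior (k+1, n-k+1) of a proportion under a uniform prior."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return (float(k + 1), float(n - k + 1))


def predicted_vs_prevalence(
    samples: PosteriorSamples,
    cohort: CohortTable,
    patterns,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    max_draws: int = 2000,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Model-predicted probability of each observable diagnosis pattern,
    per posterior draw, against the beta distribution its cohort
    prevalence implies.

    The compared quantity is the probability of *observing* the full
    pattern (hidden state pushed through the observation matrix, stages
    mixed at the cohort's early/late proportions), which is directly
    estimable from data as a prevalence — an apples-to-apples calibration
    check. Returns one row per pattern with the risk histogram, its mean,
    the beta parameters and the beta central 95% interval.
    """
    patterns = [p.validate(graph) for p in patterns]
    for p in patterns:
        if any(s is None for s in p.statuses):
            raise ValueError("calibration patterns must be fully observed")
    draws = samples.draws
    if max_draws is not None and len(draws) > max_draws:
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(len(draws), size=max_draws, replace=False)
        idx.sort()
        draws = draws[idx]
    n = len(cohort)
    w_early = cohort.n_early / n
    B = build_observation_matrix(obs, graph)
    pattern_idx = [
        int(sum(s << i for i, s in enumerate(p.statuses))) for p in patterns
    ]
    predicted = np.zeros((len(draws), len(patterns)))
    for j, row in enumerate(draws):
        theta = ParameterVector.from_array(graph, row)
        obs_dist = np.zeros(graph.n_states)
        for stage, w in (("early", w_early), ("late", 1.0 - w_early)):
            if w == 0.0:
                continue
            marg = marginal_state_distribution(theta, stage, graph, time_config)
            obs_dist += w * (marg @ B)
        predicted[j] = obs_dist[pattern_idx]
    rows = []
    from scipy import stats

    for i, p in enumerate(patterns):
        k = sum(
            1
            for r in cohort
            if tuple(r.observed) == tuple(p.statuses)
        )
        a, b = prevalence_beta(k, n)
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        rows.append(
            {
                "pattern": p.label(graph),
                "count": k,
                "n": n,
                "beta_a": a,
                "beta_b": b,
                "beta_lo95": float(lo),
                "beta_hi95": float(hi),
                "predicted_mean": float(predicted[:, i].mean()),
                "histogram": predicted[:, i],
            }
        )
    return pd.DataFrame(rows)


def _overlap_coefficient(x: np.ndarray, y: np.ndarray, bins: int = 100) -> float:
    """Integral of the min of two normalized histograms on a shared grid."""
    hx, _ = np.histogram(x, bins=bins, range=(0.0, 1.0))
    hy, _ = np.histogram(y, bins=bins, range=(0.0, 1.0))
    return float(np.minimum(hx / max(len(x), 1), hy / max(len(y), 1)).sum())


def compare_bn_hmm(
    samples_hmm: PosteriorSamples,
    samples_bn: PosteriorSamples,
    queries,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    max_draws: int = 2000,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Distance between HMM and BN risk histograms for each query.

    Each query's risk is evaluated per draw under the HMM (with the
    stage-appropriate time prior) and under the one-pass BN closed form;
    reported are the mean difference, the max per-draw |difference| on the
    paired prefix, and the histogram overlap coefficient.
    """
    if len(samples_hmm) == 0 or len(samples_bn) == 0:
        raise ValueError("both sample sets must be non-empty")

    def _subsample(draws):
        if max_draws is not None and len(draws) > max_draws:
            rng = np.random.default_rng(subsample_seed)
            idx = rng.choice(len(draws), size=max_draws, replace=False)
            idx.sort()
            return draws[idx]
        return draws

    d_hmm = _subsample(samples_hmm.draws)
    d_bn = _subsample(samples_bn.draws)
    rows = []
    for q in queries:
        r_hmm = np.array(
            [
                microscopic_risk(
                    ParameterVector.from_array(graph, row),
                    q.levels, q.diagnosis, q.stage, graph, obs, time_config,
                )
                for row in d_hmm
            ]
        )
        r_bn = np.array(
            [
                bn_risk(
                    ParameterVector.from_array(graph, row),
                    q.levels, q.diagnosis, graph, obs,
                )
                for row in d_bn
            ]
        )
        m = min(len(r_hmm), len(r_bn))
        rows.append(
            {
                "label": q.label,
                "stage": q.stage,
                "hmm_mean": float(r_hmm.mean()),
                "bn_mean": float(r_bn.mean()),
                "mean_difference": float(r_hmm.mean() - r_bn.mean()),
                "max_paired_abs_difference": float(
                    np.max(np.abs(r_hmm[:m] - r_bn[:m]))
                ),
                "overlap": _overlap_coefficient(r_hmm, r_bn),
            }
        )
    return pd.DataFrame(rows)
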