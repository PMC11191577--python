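# Methods

## Model

A patient's nodal status is a hidden binary vector over the modeled lymph
node levels (LNLs). On the default graph the levels are I–IV with drainage
arcs I→II, II→III, III→IV; every level additionally receives a tumor arc.
States are indexed with the first level as the least-significant bit, so
the 16 states of the default graph map to indices 0 (all healthy) through
15 (all involved).

**Dynamics.** Time is discrete. In one step a healthy level `v` becomes
involved with probability `p_v = 1 − (1 − b_v) ∏_r (1 − t_rv)`, the
product running over involved parents `r` of `v` — independent-failure
(noisy-OR) combination of the tumor arc and the parent arcs. Involved
levels stay involved, so transitions are monotone in the subset order and
the all-involved state is absorbing. Every transition-matrix row sums to
one and every "healing" entry is exactly zero (asserted, not approximated,
in the tests).

**Within-step cascade.** The parent set in `p_v` is evaluated in the
*destination* state: a level that becomes involved during a step can
already seed its children in that same step, with the per-level factors
multiplied in topological order. This convention was chosen deliberately.
It makes the one-pass Bayesian-network (BN) model of lymphatic spread —
hidden-state prior `P(x) = ∏_v p_v^{x_v} (1 − p_v)^{1−x_v}` evaluated in
topological order — *exactly* the distribution after one HMM step from
the healthy state, so the BN comparison is an algebraic identity at a
point-mass one-step time prior rather than an approximate empirical
observation. The alternative convention (parents read from the source
state, no cascade) is the other defensible reading; under it the two
models agree only approximately. The identity was preferred because it
gives the BN comparison an exact, testable limit. A consequence worth
knowing: after one step from the healthy state the per-level marginals are
not the raw `b_v` but include cascade terms (e.g. level II's marginal is
`1 − (1 − b_2)(1 − b_1 t_12)`).

**Observation.** Each level's MRI read is conditionally independent given
the hidden state: a truly involved level is positive with sensitivity
0.81, a healthy one negative with specificity 0.63 (meta-analysis values
for nodal staging in head and neck cancer; fixed, not learned). Unknown or
unreported level statuses are marginalized out (their observation factor
is one), never imputed negative.

**Diagnosis time.** The number of progression steps elapsed at diagnosis
is unobserved and carries a `Binomial(t_max, p)` prior with `t_max = 10`.
`p_early = 0.3` is fixed in configuration and anchors the time scale;
`p_late` is a learned parameter. Fixing one of the two avoids the
non-identifiability of an overall time-scale shift. `t_max = 10` is large
enough that occupancy curves are smooth while keeping the likelihood a
short sum; it is configurable.

**Likelihood.** A patient's likelihood is
`Σ_x P(diagnosis | x) Σ_t prior(t) P(X_t = x)`; the cohort log-likelihood
sums over patients and is `−inf` (not an exception) if any patient is
impossible under the parameters. All probability arithmetic is linear —
with 16-state vectors underflow is not a concern — and only the cohort sum
is taken in logs. For MCMC the cohort is compiled to per-stage diagnosis-
pattern counts, making each likelihood evaluation independent of cohort
size.

## Inference

Uniform prior on the closed unit hypercube for all parameters
`(b_1..b_4, t_12, t_23, t_34, p_late)`. Sampling uses the affine-invariant
ensemble sampler (emcee) with defaults of 10× parameter-count walkers,
2000 burn-in steps discarded and 10 000 retained, thinning 1; walkers
start uniform in `[0.1, 0.9]^d` from a seeded generator and the whole run
is deterministic given the seed. The mean acceptance fraction and the
integrated autocorrelation time are recorded in the output metadata, and a
warning is logged when the retained chain is shorter than 50× the
autocorrelation estimate. Parameters the data do not inform (e.g. `b4`
when level IV is never observed positive) revert to the uniform prior —
documented behavior, not an error.

Summaries report mean, standard deviation and the 16th/84th percentiles
per parameter. Correlation matrices mark numerically constant parameters
as missing rather than zero.

The package-internal recovery and cross-validation runs use smaller,
explicitly configured chains (e.g. 32 walkers × 4000 retained steps for
the 2000-patient recovery experiment, 18–24 walkers × a few hundred steps
for CV plumbing); these sizes are stated in the scripts and tests that use
them and were chosen so a full run completes in minutes on one core.

## Risk prediction

`P(x | ζ, stage) ∝ P(ζ | x) · P(x | stage)` with the time-marginalized
state distribution as prior; the risk of one level (or of several levels
jointly) is the posterior mass on states where the target levels are all
involved. Risks are reported per posterior draw (histograms) plus
posterior-mean point estimates formatted as percentages with two decimals.
The standard conditioning grid (N0, "II only", "II and III", "III only")
interprets each pattern as a full four-level diagnosis with unlisted
levels observed negative. Risk tables subsample at most 2000 seeded draws
per query; full-chain evaluation adds nothing but runtime.

A diagnosis with zero probability under the parameters makes the
posterior undefined and raises an error rather than returning a value.

## Synthetic cohorts

The generator draws diagnosis time from the stage's binomial prior,
evolves the hidden state through the same cascade kernel (sampling levels
in topological order within each step), and corrupts the truth through the
sensitivity/specificity model; T-stage is uniform within the stage class
(early = T1–T2, late = T3–T4). Default generating parameters:
`b = (0.39, 0.53, 0.03, 0.01)`, `t = (0.5, 0.3, 0.2)`, `p_late = 0.6`.
The base probabilities follow literature point estimates for OTSCC except
that `b4` is 0.01 instead of the reported 0.00 so level-IV inference stays
non-degenerate (the reported values are available as a preset); the `t`
values and `p_late` are synthetic choices that produce the clinically
expected II ≥ I ≥ III ≥ IV prevalence ordering. The default emulated
series is 108 patients at 66 early / 42 late (55.6% early).

What the generator does *not* emulate: inter-reader variability, level-
dependent or size-dependent sensitivity, pathology ground truth for
dissected levels, skip metastases outside the modeled arcs, bilateral
spread, and covariates (age, sex, HPV, areca-nut history). Passing tests
therefore demonstrate internal consistency of model + inference + risk
machinery, not clinical validity on real cohorts.

## Evaluation

Threefold cross-validation splits the cohort into three near-equal folds,
stratified by stage class so each fold preserves the early/late mix (a
plain random split at n ≈ 100 can produce stage-degenerate folds); each
pair of folds is fitted and the held-out third scored. Held-out, training
and whole-cohort log-likelihoods are evaluated at the posterior mean of
the relevant fit — the posterior-mean plug-in is one defensible choice
among several (maximum-posterior draw, full predictive average) and the
ingredients to compute the others are exposed.

Calibration compares, per posterior draw, the model-predicted probability
of *observing* a full diagnosis pattern (hidden marginal pushed through
the observation matrix, stages mixed at the cohort's proportions) with the
`Beta(k+1, n−k+1)` posterior of that pattern's cohort prevalence under a
uniform prior. The observable-pattern probability was chosen over
hidden-state risk so both sides of the comparison estimate the same
quantity. Histogram distances for the BN-vs-HMM comparison use the mean
difference and the overlap coefficient (integral of the pointwise minimum
of the two normalized histograms on a fixed 100-bin grid over [0, 1]).

## Numerical notes and limitations

- Matrix construction is fully vectorized over the `2^V × 2^V` state
  space; practical up to `V ≈ 10`, far beyond the 4 levels used here.
- Determinism: identical (config, seed, inputs) reproduce byte-identical
  CSV/JSON outputs; floats round-trip through CSV at full precision.
- Identifiability is limited by the noisy observation model: with
  specificity 0.63, a level's base probability and the spread from its
  parent (`b_v` vs `t_{pa(v),v}`) are strongly anti-correlated in the
  posterior, and at a 2000-patient cohort the posterior mean can sit more
  than 0.1 from the generating value along these ridges even though
  credible intervals cover the truth. Recovery experiments should be read
  with interval coverage, not point error, as the primary metric.
- The model is unilateral and covers levels I–IV only; levels V–VII,
  contralateral spread, multi-modality imaging, and continuous-time
  formulations are out of scope.
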