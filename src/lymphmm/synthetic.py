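"""Synthetic cohorts with the exact generative structure the model assumes.

The generator draws, per patient, a diagnosis time from the stage-specific
binomial prior, evolves the hidden involvement pattern that many steps
through the monotone transition kernel (sampling levels in topological
order within each step, so within-step cascade matches the kernel), and
corrupts the true state through the sensitivity/specificity observation
model. Cohorts round-trip losslessly through a plain CSV schema:

    patient_id,t_stage,lvl_I,lvl_II,lvl_III,lvl_IV[,true_I..,time_step]

with statuses 0/1/NA and provenance stored in leading ``#`` comment lines.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import LymphGraph, build_default_graph
from .hmm import (
    Diagnosis,
    ObservationModel,
    ParameterVector,
    TimeConfig,
    binomial_time_prior,
)

__all__ = [
    "PatientRecord",
    "CohortTable",
    "default_generator_theta",
    "reported_base_probabilities",
    "simulate_patient",
    "simulate_trajectory",
    "simulate_cohort",
    "read_cohort",
    "write_cohort",
]

EARLY_T_STAGES = (1, 2)
LATE_T_STAGES = (3, 4)


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the schema."""


def default_generator_theta() -> ParameterVector:
    """Generating parameters for the default four-level graph.

    The base probabilities follow literature-reported point estimates for
    oral tongue SCC (b1=0.39, b2=0.53, b3=0.03) except that b4 is set to a
    small nonzero 0.01 so level-IV inference stays non-degenerate; the
    transition probabilities t=(0.5, 0.3, 0.2) and p_late=0.6 are synthetic
    choices producing the clinically expected II >= I >= III >= IV
    prevalence ordering, not estimates.
    """
    return ParameterVector(b=(0.39, 0.53, 0.03, 0.01), t=(0.5, 0.3, 0.2), p_late=0.6)


def reported_base_probabilities() -> tuple[float, ...]:
    """Literature point estimates of b1..b4 for the default graph (b4 = 0)."""
    return (0.39, 0.53, 0.03, 0.0)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: T-stage, observed per-level diagnosis, optional truth."""

    patient_id: str
    t_stage: int
    observed: tuple[int | None, ...]
    true_state: tuple[int, ...] | None = None
    time_step: int | None = None

    def __post_init__(self) -> None:
        if self.t_stage not in (*EARLY_T_STAGES, *LATE_T_STAGES):
            raise CohortValidationError(
                f"patient {self.patient_id}: t_stage must be 1-4, got {self.t_stage}"
            )
        for s in self.observed:
            if s not in (0, 1, None):
                raise CohortValidationError(
                    f"patient {self.patient_id}: observed status {s!r} not in {{0,1,NA}}"
                )
        if self.true_state is not None:
            if len(self.true_state) != len(self.observed):
                raise CohortValidationError(
                    f"patient {self.patient_id}: true_state length mismatch"
                )
            if any(s not in (0, 1) for s in self.true_state):
                raise CohortValidationError(
                    f"patient {self.patient_id}: true_state must be 0/1"
                )

    @property
    def stage_class(self) -> str:
        return "early" if self.t_stage in EARLY_T_STAGES else "late"

    def diagnosis(self, graph: LymphGraph) -> Diagnosis:
        return Diagnosis(self.observed).validate(graph)


@dataclass
class CohortTable:
    """Ordered patient records plus generation provenance (if synthetic)."""

    records: list[PatientRecord]
    levels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dup}")
        for r in self.records:
            if len(r.observed) != len(self.levels):
                raise CohortValidationError(
                    f"patient {r.patient_id}: {len(r.observed)} level statuses "
                    f"for {len(self.levels)} levels"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices) -> "CohortTable":
        return CohortTable(
            records=[self.records[i] for i in indices],
            levels=self.levels,
            provenance=dict(self.provenance, subset=True),
        )

    @property
    def n_early(self) -> int:
        return sum(r.stage_class == "early" for r in self.records)

    @property
    def n_late(self) -> int:
        return sum(r.stage_class == "late" for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        has_truth = all(r.true_state is not None for r in self.records)
        rows = []
        for r in self.records:
            row: dict = {"patient_id": r.patient_id, "t_stage": r.t_stage}
            for v, s in zip(self.levels, r.observed):
                row[f"lvl_{v}"] = s
            if has_truth:
                for v, s in zip(self.levels, r.true_state):
                    row[f"true_{v}"] = s
                row["time_step"] = r.time_step
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _step(state, theta, graph, topo, rng):
    """Advance one time step in place; topological order gives in-step cascade."""
    for v in topo:
        i = graph.level_index(v)
        if state[i] == 1:
            continue
        stay = 1.0 - theta.base(graph, v)
        for parent, _ in graph.parents(v):
            if state[graph.level_index(parent)] == 1:
                stay *= 1.0 - theta.spread(graph, parent, v)
        if rng.random() < 1.0 - stay:
            state[i] = 1


def simulate_trajectory(
    theta: ParameterVector,
    n_steps: int,
    graph: LymphGraph,
    rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    """Hidden-state path of length ``n_steps + 1`` starting all-healthy."""
    topo = graph.topological_levels()
    state = [0] * graph.n_levels
    path = [tuple(state)]
    for _ in range(n_steps):
        _step(state, theta, graph, topo, rng)
        path.append(tuple(state))
    return path


def simulate_patient(
    theta: ParameterVector,
    stage: str,
    graph: LymphGraph,
    obs: ObservationModel,
    time_config: TimeConfig,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> PatientRecord:
    """Draw one patient: diagnosis time, hidden trajectory, noisy observation."""
    if stage not in ("early", "late"):
        raise ValueError(f"stage must be 'early' or 'late', got {stage!r}")
    p = time_config.p_early if stage == "early" else theta.p_late
    prior = binomial_time_prior(time_config.t_max, p)
    t = int(rng.choice(prior.t_max + 1, p=np.asarray(prior.weights)))
    truth = simulate_trajectory(theta, t, graph, rng)[-1]
    observed = tuple(
        int(rng.random() < (obs.sensitivity if x == 1 else 1.0 - obs.specificity))
        for x in truth
    )
    stages = EARLY_T_STAGES if stage == "early" else LATE_T_STAGES
    t_stage = int(rng.choice(stages))
    return PatientRecord(
        patient_id=patient_id,
        t_stage=t_stage,
        observed=observed,
        true_state=truth,
        time_step=t,
    )


def simulate_cohort(
    theta: ParameterVector,
    n_early: int,
    n_late: int,
    seed: int,
    graph: LymphGraph | None = None,
    obs: ObservationModel | None = None,
    time_config: TimeConfig | None = None,
) -> CohortTable:
    """Simulate ``n_early + n_late`` patients; deterministic given ``seed``.

    The default cohort size emulating the modeled clinical series is 66
    early / 42 late (108 total with the reported 55.6% early fraction).
    """
    if n_early + n_late < 1:
        raise ValueError("cohort must contain at least one patient")
    graph = graph or build_default_graph()
    obs = obs or ObservationModel()
    time_config = time_config or TimeConfig()
    rng = np.random.default_rng(seed)
    records = []
    stages = ["early"] * n_early + ["late"] * n_late
    width = max(4, len(str(len(stages))))
    for i, stage in enumerate(stages):
        records.append(
            simulate_patient(
                theta, stage, graph, obs, time_config, rng,
                patient_id=f"P{i + 1:0{width}d}",
            )
        )
    provenance = {
        "generator": "lymphmm.synthetic.simulate_cohort",
        "theta": {"b": list(theta.b), "t": list(theta.t), "p_late": theta.p_late},
        "seed": int(seed),
        "n_early": int(n_early),
        "n_late": int(n_late),
        "observation": {
            "sensitivity": obs.sensitivity,
            "specificity": obs.specificity,
        },
        "time": {"t_max": time_config.t_max, "p_early": time_config.p_early},
        "levels": list(graph.levels),
    }
    return CohortTable(records=records, levels=graph.levels, provenance=provenance)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort CSV; provenance goes into leading # comment lines."""
    frame = cohort.to_frame()
    buf = io.StringIO()
    if cohort.provenance:
        buf.write("# provenance: " + json.dumps(cohort.provenance, sort_keys=True) + "\n")
    buf.write("# levels: " + json.dumps(list(cohort.levels)) + "\n")
    frame.to_csv(buf, index=False, na_rep="NA")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _parse_status(raw, patient_row: int, column: str):
    if pd.isna(raw) or (isinstance(raw, str) and raw.strip().upper() == "NA"):
        return None
    try:
        val = int(raw)
    except (TypeError, ValueError):
        val = -1
    if val not in (0, 1):
        raise CohortValidationError(
            f"row {patient_row}, column {column}: status {raw!r} not in {{0,1,NA}}"
        )
    return val


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made).

    Malformed rows raise :class:`CohortValidationError` naming the row and
    column; duplicate patient ids are rejected.
    """
    text = Path(path).read_text(encoding="utf-8")
    provenance: dict = {}
    levels: list[str] | None = None
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("# ").strip()
        if body.startswith("provenance:"):
            provenance = json.loads(body[len("provenance:"):])
        elif body.startswith("levels:"):
            levels = json.loads(body[len("levels:"):])
    frame = pd.read_csv(io.StringIO(text), comment="#", dtype={"patient_id": str})
    required = {"patient_id", "t_stage"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortValidationError(f"missing required columns: {sorted(missing)}")
    level_cols = [c for c in frame.columns if c.startswith("lvl_")]
    if not level_cols:
        raise CohortValidationError("no lvl_<level> status columns found")
    if levels is None:
        levels = [c[len("lvl_"):] for c in level_cols]
    expected_cols = [f"lvl_{v}" for v in levels]
    missing_lvls = set(expected_cols) - set(level_cols)
    if missing_lvls:
        raise CohortValidationError(f"missing level columns: {sorted(missing_lvls)}")
    truth_cols = [f"true_{v}" for v in levels]
    has_truth = all(c in frame.columns for c in truth_cols) and "time_step" in frame.columns
    records = []
    for i, row in frame.iterrows():
        rownum = i + 1
        try:
            t_stage = int(row["t_stage"])
        except (TypeError, ValueError):
            raise CohortValidationError(
                f"row {rownum}, column t_stage: {row['t_stage']!r} is not an integer"
            ) from None
        observed = tuple(
            _parse_status(row[c], rownum, c) for c in expected_cols
        )
        true_state = None
        time_step = None
        if has_truth:
            true_state = tuple(
                _parse_status(row[c], rownum, c) for c in truth_cols
            )
            time_step = int(row["time_step"])
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    t_stage=t_stage,
                    observed=observed,
                    true_state=true_state,
                    time_step=time_step,
                )
            )
        except CohortValidationError as err:
            raise CohortValidationError(f"row {rownum}: {err}") from None
    return CohortTable(records=records, levels=tuple(levels), provenance=provenance)
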