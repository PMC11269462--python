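"""Standardized mean differences for two-arm medication studies.

Each study contributes one effect size per outcome: the difference between the
medication and control arm means divided by the pooled standard deviation
(Hedges' g), multiplied by the small-sample correction factor
``J = 1 - 3 / (4(n1 + n2) - 9)`` to give the unbiased standardized mean
difference d. Signs are arranged so that, for every outcome, a *negative*
effect size favours the medication; the one outcome scored in the opposite
direction (percent days abstinent, where more is better) is flipped.

Raw outcomes are amalgamated into two composite clinical-trial endpoints:
``heavy_drinking`` (return to heavy drinking, percent heavy drinking days,
drinks per week / day / drinking day) and ``abstinence`` (return to any
drinking, percent days abstinent). Laboratory cue-induced craving maps to its
own ``cue_craving`` endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StudyRecord",
    "EffectSize",
    "hedges_g",
    "small_sample_correction",
    "effect_size_variance",
    "apply_sign_convention",
    "map_to_endpoint",
    "study_effect_size",
    "effects_frame",
    "read_studies_csv",
    "read_precomputed_csv",
    "write_effects_csv",
    "read_effects_csv",
]

ENDPOINT_BY_OUTCOME = {
    "cue_craving": "cue_craving",
    "return_heavy_drinking": "heavy_drinking",
    "pct_heavy_days": "heavy_drinking",
    "drinks_per_week": "heavy_drinking",
    "drinks_per_day": "heavy_drinking",
    "drinks_per_drinking_day": "heavy_drinking",
    "return_any_drinking": "abstinence",
    "pct_days_abstinent": "abstinence",
}

#: Outcomes scored "more is better"; their d is negated so that negative
#: always favours the medication.
SIGN_FLIPPED_OUTCOMES = frozenset({"pct_days_abstinent"})

PARADIGMS = frozenset({"cue_reactivity", "rct"})
DESIGNS = frozenset({"parallel", "crossover"})

STUDIES_CSV_COLUMNS = [
    "study_id", "medication", "paradigm", "outcome", "design",
    "n_med", "mean_med", "sd_med", "n_ctrl", "mean_ctrl", "sd_ctrl",
]
PRECOMPUTED_CSV_COLUMNS = [
    "study_id", "medication", "paradigm", "outcome", "d", "se",
]
EFFECTS_CSV_COLUMNS = [
    "medication", "endpoint", "outcome", "study_id", "d", "variance",
    "sign_flipped", "crossover",
]


@dataclass(frozen=True)
class StudyRecord:
    """Two-arm summary statistics for one study and one outcome."""

    study_id: str
    medication: str
    paradigm: str
    outcome: str
    design: str
    n_med: int
    mean_med: float
    sd_med: float
    n_ctrl: int
    mean_ctrl: float
    sd_ctrl: float

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.outcome not in ENDPOINT_BY_OUTCOME:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_med < 2 or self.n_ctrl < 2:
            raise ValueError("each arm needs at least 2 participants")
        if self.sd_med < 0 or self.sd_ctrl < 0:
            raise ValueError("arm SDs must be non-negative")
        if self.sd_med == 0 and self.sd_ctrl == 0:
            raise ValueError(
                f"study {self.study_id!r}: both arm SDs are zero, the pooled "
                "SD and hence the effect size are undefined"
            )


@dataclass(frozen=True)
class EffectSize:
    """One study's unbiased standardized mean difference, direction applied."""

    value: float
    variance: float
    medication: str
    endpoint: str
    outcome: str
    study_id: str
    sign_flipped: bool
    crossover: bool = False

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("effect size variance must be positive")


def hedges_g(rec: StudyRecord) -> float:
    """Raw standardized mean difference (medication minus control)."""
    num = rec.mean_med - rec.mean_ctrl
    pooled_var = (
        (rec.n_med - 1) * rec.sd_med**2 + (rec.n_ctrl - 1) * rec.sd_ctrl**2
    ) / (rec.n_med + rec.n_ctrl - 2)
    if pooled_var <= 0:
        raise ValueError("degenerate pooled SD: effect size undefined")
    return num / math.sqrt(pooled_var)


def small_sample_correction(n_med: int, n_ctrl: int) -> float:
    """Bias-correction factor J = 1 - 3/(4N - 9), N the total sample size."""
    total = n_med + n_ctrl
    if total < 4:
        raise ValueError("total sample size must be at least 4")
    return 1.0 - 3.0 / (4.0 * total - 9.0)


def effect_size_variance(d: float, n_med: int, n_ctrl: int) -> float:
    """Large-sample sampling variance of a standardized mean difference."""
    total = n_med + n_ctrl
    return total / (n_med * n_ctrl) + d * d / (2.0 * total)


def apply_sign_convention(d: float, outcome: str) -> float:
    """Orient d so a negative value favours the medication for any outcome."""
    if outcome not in ENDPOINT_BY_OUTCOME:
        raise ValueError(f"unknown outcome {outcome!r}")
    return -d if outcome in SIGN_FLIPPED_OUTCOMES else d


def map_to_endpoint(outcome: str) -> str:
    """Map a raw outcome label onto its composite analysis endpoint."""
    try:
        return ENDPOINT_BY_OUTCOME[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}") from None


def study_effect_size(rec: StudyRecord) -> EffectSize:
    """Unbiased d with its variance, sign convention and endpoint applied."""
    g = hedges_g(rec)
    d = g * small_sample_correction(rec.n_med, rec.n_ctrl)
    d = apply_sign_convention(d, rec.outcome)
    var = effect_size_variance(d, rec.n_med, rec.n_ctrl)
    return EffectSize(
        value=d,
        variance=var,
        medication=rec.medication,
        endpoint=map_to_endpoint(rec.outcome),
        outcome=rec.outcome,
        study_id=rec.study_id,
        sign_flipped=rec.outcome in SIGN_FLIPPED_OUTCOMES,
        crossover=rec.design == "crossover",
    )


def effects_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Compute effect sizes for a collection of study records.

    Crossover studies are handled by treating the two conditions as
    independent arms (no within-subject correlation term is available from
    condition-level summaries); such rows carry ``crossover=True``.
    """
    rows = [study_effect_size(rec) for rec in records]
    frame = pd.DataFrame(
        [
            {
                "medication": e.medication,
                "endpoint": e.endpoint,
                "outcome": e.outcome,
                "study_id": e.study_id,
                "d": e.value,
                "variance": e.variance,
                "sign_flipped": e.sign_flipped,
                "crossover": e.crossover,
            }
            for e in rows
        ],
        columns=EFFECTS_CSV_COLUMNS,
    )
    return frame


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s): {', '.join(missing)}")


def read_studies_csv(path) -> list[StudyRecord]:
    """Read study-level arm summaries; raises naming any missing column."""
    frame = pd.read_csv(path)
    _require_columns(frame, STUDIES_CSV_COLUMNS, "studies csv")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    medication=str(row["medication"]),
                    paradigm=str(row["paradigm"]),
                    outcome=str(row["outcome"]),
                    design=str(row["design"]),
                    n_med=int(row["n_med"]),
                    mean_med=float(row["mean_med"]),
                    sd_med=float(row["sd_med"]),
                    n_ctrl=int(row["n_ctrl"]),
                    mean_ctrl=float(row["mean_ctrl"]),
                    sd_ctrl=float(row["sd_ctrl"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"studies csv row {i}: {exc}") from exc
    return records


def read_precomputed_csv(path) -> pd.DataFrame:
    """Read pre-computed (d, se) rows, e.g. for binary relapse outcomes.

    Returns a frame in the ``effects.csv`` schema with variance = se**2.
    The sign convention is assumed to be already applied by the supplier.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, PRECOMPUTED_CSV_COLUMNS, "precomputed effects csv")
    bad = frame.index[frame["se"] <= 0].tolist()
    if bad:
        raise ValueError(f"precomputed effects csv rows {bad}: se must be > 0")
    out = pd.DataFrame(
        {
            "medication": frame["medication"].astype(str),
            "endpoint": frame["outcome"].map(map_to_endpoint),
            "outcome": frame["outcome"],
            "study_id": frame["study_id"].astype(str),
            "d": frame["d"].astype(float),
            "variance": frame["se"].astype(float) ** 2,
            "sign_flipped": frame["outcome"].isin(SIGN_FLIPPED_OUTCOMES),
            "crossover": False,
        },
        columns=EFFECTS_CSV_COLUMNS,
    )
    return out


def write_effects_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_effects_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, EFFECTS_CSV_COLUMNS[:6], "effects csv")
    return frame
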