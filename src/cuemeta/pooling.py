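"""Random-effects pooling of effect sizes within medication and endpoint.

Between-study heterogeneity is estimated with the DerSimonian-Laird moment
estimator, truncated at zero; a single-study medication has its heterogeneity
fixed at zero by convention. Pooling uses inverse-variance weights
``1 / (v_i + tau2)`` with no small-sample adjustment of the pooled standard
error (plain DL, no Knapp-Hartung).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MedicationEffect", "dl_tau2", "pool_random_effects", "pool_by_medication"]

MEDICATION_EFFECTS_COLUMNS = [
    "medication", "endpoint", "d_pooled", "se_pooled", "k", "tau2",
]


@dataclass(frozen=True)
class MedicationEffect:
    """A medication-by-endpoint pooled effect: the unit of the meta-regression."""

    medication: str
    endpoint: str
    d_pooled: float
    se_pooled: float
    k: int
    tau2: float

    def __post_init__(self) -> None:
        if not self.se_pooled > 0:
            raise ValueError("pooled standard error must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.k == 1 and self.tau2 != 0:
            raise ValueError("a single effect size implies tau2 = 0")


def _as_arrays(d: Sequence[float], variance: Sequence[float]):
    d = np.asarray(d, dtype=float)
    v = np.asarray(variance, dtype=float)
    if d.size == 0:
        raise ValueError("at least one effect size is required")
    if d.shape != v.shape:
        raise ValueError("d and variance must have the same length")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    return d, v


def dl_tau2(d: Sequence[float], variance: Sequence[float]) -> float:
    """DerSimonian-Laird between-study variance, truncated at zero.

    With k = 1 the heterogeneity is fixed at 0 (nothing to estimate).
    """
    d, v = _as_arrays(d, variance)
    k = d.size
    if k == 1:
        return 0.0
    w = 1.0 / v
    d_fixed = np.sum(w * d) / np.sum(w)
    q = np.sum(w * (d - d_fixed) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / denom))


def pool_random_effects(
    d: Sequence[float],
    variance: Sequence[float],
    medication: str = "",
    endpoint: str = "",
) -> MedicationEffect:
    """Inverse-variance random-effects pooled estimate with DL heterogeneity."""
    d, v = _as_arrays(d, variance)
    tau2 = dl_tau2(d, v)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * d) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MedicationEffect(
        medication=medication,
        endpoint=endpoint,
        d_pooled=pooled,
        se_pooled=se,
        k=int(d.size),
        tau2=tau2,
    )


def pool_by_medication(effects: pd.DataFrame) -> pd.DataFrame:
    """Pool an ``effects.csv``-schema frame per medication and endpoint.

    Every outcome-level effect size enters as an independent unit (no
    within-study collapsing), so k counts effect sizes, not studies.
    """
    rows = []
    for (med, endpoint), grp in effects.groupby(["medication", "endpoint"], sort=True):
        pooled = pool_random_effects(
            grp["d"].to_numpy(), grp["variance"].to_numpy(), med, endpoint
        )
        rows.append(
            {
                "medication": pooled.medication,
                "endpoint": pooled.endpoint,
                "d_pooled": pooled.d_pooled,
                "se_pooled": pooled.se_pooled,
                "k": pooled.k,
                "tau2": pooled.tau2,
            }
        )
    return pd.DataFrame(rows, columns=MEDICATION_EFFECTS_COLUMNS)
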