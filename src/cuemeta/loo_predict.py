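"""Leave-one-out predictive distributions for clinical-trial effect sizes.

For each medication the regression is refitted on the remaining medications
(warm-started at the full-sample slope, so each refit tracks the same branch
of the non-convex objective the full fit sits on). The held-out medication's
clinical-trial effect size is then predicted by propagating only its
cue-craving effect size's sampling error through the frozen refitted line:
craving values are drawn from ``N(x_i, sx_i^2)`` and mapped through
``a + b x``. The spread of those draws is therefore ``|b| * sx_i`` exactly,
and the reported ``se_prediction`` is that closed form.

Coverage is scored by whether the observed pooled clinical-trial effect size
falls inside the central ``level`` (default 95%) quantile interval of the
draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .wy_regression import RegressionFit, RegressionInput, predict_rct_effect, wy_fit

__all__ = ["PredictiveDistribution", "loo_all", "coverage_check", "loo_frame"]

DEFAULT_DRAWS = 10_000


@dataclass
class PredictiveDistribution:
    medication: str
    endpoint: str
    draws: np.ndarray
    point_prediction: float
    se_prediction: float      # |slope| * craving SE (closed form)
    draw_mean: float
    draw_sd: float
    observed_d: float
    observed_se: float
    covered: bool
    interval: tuple[float, float]
    level: float
    loo_fit: RegressionFit


def coverage_check(pd_: PredictiveDistribution) -> bool:
    """True iff the observed effect lies in the central interval of the draws."""
    lo, hi = pd_.interval
    return bool(lo <= pd_.observed_d <= hi)


def loo_all(
    inp: RegressionInput,
    draws: int = DEFAULT_DRAWS,
    seed: Optional[int] = None,
    *,
    level: float = 0.95,
    full_fit: Optional[RegressionFit] = None,
) -> list[PredictiveDistribution]:
    """Predictive distribution of each medication's clinical-trial effect."""
    if inp.n_points < 4:
        raise ValueError("leave-one-out needs at least 4 points")
    if full_fit is None:
        full_fit = wy_fit(inp, select="positive")
    rng = np.random.default_rng(seed)
    out = []
    alpha_tail = (1.0 - level) / 2.0
    for i, med in enumerate(inp.labels):
        sub = inp.drop(i)
        fit = wy_fit(sub, init=full_fit.slope, select="init")
        x_i, sx_i = float(inp.x[i]), float(inp.sx[i])
        xs = rng.normal(x_i, sx_i, size=draws)
        ys = fit.intercept + fit.slope * xs
        point = float(predict_rct_effect(fit, x_i))
        lo, hi = np.quantile(ys, [alpha_tail, 1.0 - alpha_tail])
        pd_ = PredictiveDistribution(
            medication=med,
            endpoint=inp.endpoint,
            draws=ys,
            point_prediction=point,
            se_prediction=abs(fit.slope) * sx_i,
            draw_mean=float(np.mean(ys)),
            draw_sd=float(np.std(ys, ddof=1)),
            observed_d=float(inp.y[i]),
            observed_se=float(inp.sy[i]),
            covered=bool(lo <= inp.y[i] <= hi),
            interval=(float(lo), float(hi)),
            level=level,
            loo_fit=fit,
        )
        out.append(pd_)
    return out


def loo_frame(dists: list[PredictiveDistribution]) -> pd.DataFrame:
    """Tabular summary (one row per medication) of LOO predictions."""
    return pd.DataFrame(
        {
            "medication": [d.medication for d in dists],
            "endpoint": [d.endpoint for d in dists],
            "observed_d": [d.observed_d for d in dists],
            "observed_se": [d.observed_se for d in dists],
            "predicted_d": [d.point_prediction for d in dists],
            "predicted_se": [d.se_prediction for d in dists],
            "loo_slope": [d.loo_fit.slope for d in dists],
            "loo_converged": [d.loo_fit.converged for d in dists],
            "covered": [d.covered for d in dists],
        }
    )
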