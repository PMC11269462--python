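"""Williamson-York straight-line fit with errors in both variables.

The line ``y = a + b x`` is estimated by minimizing the weighted objective

    S(a, b) = sum_i W_i(b) (y_i - a - b x_i)^2,
    W_i(b) = 1 / (sy_i^2 + b^2 sx_i^2)

(York's formulation with zero error correlation between the axes). Because
the weights depend on the slope, S is generally non-convex in b; on sparse,
noisy data it can carry several local minima of opposite sign. The module
therefore exposes three ways of choosing the solution:

* ``select="init"`` - classic fixed-point iteration from a starting slope,
  tracking whatever solution that basin holds (used to warm-start
  leave-one-out refits at the full-sample slope);
* ``select="global"`` - scan the profile objective S(b) over all slopes and
  return the global minimum (the package default);
* ``select="positive"`` - among local minima with b > 0, return the one with
  the smallest objective, falling back to the global minimum if none exists.
  This tracks the branch consistent with a one-sided alternative b > 0 and is
  what the reference cue-craving analysis uses.

Two standard errors are reported for each coefficient: the analytic York
(2004) value (``se_slope_raw``), which takes the stated per-point errors at
face value, and that value expanded by ``sqrt(S / (n - 2))`` (``se_slope``),
which inflates the errors so the reduced chi-square equals one. Inference
(one-sided Wald z against an upper-tail normal) uses the expanded SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RegressionInput",
    "RegressionFit",
    "york_objective",
    "wls_slope",
    "wy_fit",
    "wald_one_sided",
    "predict_rct_effect",
]

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 200
DEFAULT_ALPHA = 0.025  # 0.05 split over the two endpoint regressions
ONE_SIDED_CRITICAL = 1.64


@dataclass
class RegressionInput:
    """Per-medication (x, y) pairs with their standard errors."""

    x: np.ndarray
    y: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    labels: list[str] = field(default_factory=list)
    endpoint: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        n = self.x.size
        if not (self.y.size == self.sx.size == self.sy.size == n):
            raise ValueError("x, y, sx, sy must have equal length")
        if n < 3:
            raise ValueError("at least 3 points are required (2 coefficients + 1 df)")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("all standard errors must be positive")
        if not self.labels:
            self.labels = [f"p{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels must match the number of points")

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    def drop(self, index: int) -> "RegressionInput":
        keep = np.arange(self.n_points) != index
        return RegressionInput(
            x=self.x[keep], y=self.y[keep], sx=self.sx[keep], sy=self.sy[keep],
            labels=[l for i, l in enumerate(self.labels) if keep[i]],
            endpoint=self.endpoint,
        )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    se_slope_raw: float
    se_intercept_raw: float
    scale: float              # sqrt(S / (n - 2)), the error-expansion factor
    objective: float          # S at the solution
    z: float
    p_one_sided: float
    alpha: float
    n_points: int
    n_iter: int
    converged: bool
    selection: str            # "init", "global", "positive", "global_fallback"
    endpoint: str = ""


def york_objective(b: float, x, y, sx, sy) -> tuple[float, float]:
    """Profile objective: S minimized over the intercept at fixed slope b.

    Returns ``(S, a)`` with ``a`` the profiling intercept.
    """
    w = 1.0 / (sy**2 + b * b * sx**2)
    sw = np.sum(w)
    a = (np.sum(w * y) - b * np.sum(w * x)) / sw
    s = float(np.sum(w * (y - a - b * x) ** 2))
    return s, float(a)


def wls_slope(x, y, sy) -> float:
    """Weighted least-squares slope of y on x with weights 1/sy^2."""
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    xm = np.sum(w * x) / np.sum(w)
    ym = np.sum(w * y) / np.sum(w)
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise ValueError("x values are all identical; slope undefined")
    return float(np.sum(w * (x - xm) * (y - ym)) / sxx)


def _york_update(b, x, y, sx, sy):
    """One fixed-point update of the slope (York's iterative scheme, r = 0)."""
    wx = 1.0 / sx**2
    wy = 1.0 / sy**2
    w = wx * wy / (wx + b * b * wy)
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    u = x - xbar
    v = y - ybar
    beta = w * (u / wy + b * v / wx)
    return float(np.sum(w * beta * v) / np.sum(w * beta * u))


def _york_iterate(x, y, sx, sy, b0, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER):
    """Iterate the slope update to a fixed point; returns (b, n_iter, ok)."""
    b = float(b0)
    for it in range(1, max_iter + 1):
        b_new = _york_update(b, x, y, sx, sy)
        if abs(b_new - b) < tol:
            return b_new, it, True
        b = b_new
    return b, max_iter, False


def _york_eval(x, y, sx, sy, b):
    """York point estimates and standard errors at a given slope."""
    wx = 1.0 / sx**2
    wy = 1.0 / sy**2
    w = wx * wy / (wx + b * b * wy)
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    a = ybar - b * xbar
    u = x - xbar
    v = y - ybar
    beta = w * (u / wy + b * v / wx)
    x_adj = xbar + beta
    xm = np.sum(w * x_adj) / sw
    u_adj = x_adj - xm
    var_b = 1.0 / np.sum(w * u_adj**2)
    var_a = 1.0 / sw + xm * xm * var_b
    s = float(np.sum(w * (y - a - b * x) ** 2))
    n = x.size
    scale = math.sqrt(s / (n - 2)) if n > 2 else float("nan")
    return {
        "intercept": float(a),
        "se_slope_raw": math.sqrt(var_b),
        "se_intercept_raw": math.sqrt(var_a),
        "objective": s,
        "scale": scale,
    }


def _stationary_minima(x, y, sx, sy, n_grid=2001):
    """Local minima of the profile objective S(b) over the whole slope line.

    The slope axis is scanned through ``b = tan(theta)`` so that arbitrarily
    steep lines are covered; each bracketed minimum is refined by bounded
    scalar minimization.
    """
    eps = 1e-6
    thetas = np.linspace(-math.pi / 2 + eps, math.pi / 2 - eps, n_grid)
    bs = np.tan(thetas)
    w = 1.0 / (sy[None, :] ** 2 + bs[:, None] ** 2 * sx[None, :] ** 2)
    sw = w.sum(axis=1)
    a = ((w * y).sum(axis=1) - bs * (w * x).sum(axis=1)) / sw
    s = (w * (y[None, :] - a[:, None] - bs[:, None] * x[None, :]) ** 2).sum(axis=1)
    interior = np.where((s[1:-1] < s[:-2]) & (s[1:-1] <= s[2:]))[0] + 1
    minima = []
    for i in interior:
        res = optimize.minimize_scalar(
            lambda b: york_objective(b, x, y, sx, sy)[0],
            bounds=(bs[i - 1], bs[i + 1]),
            method="bounded",
            options={"xatol": 1e-13},
        )
        minima.append((float(res.x), float(res.fun)))
    if not minima:  # monotone profile (degenerate); fall back to grid argmin
        i = int(np.argmin(s))
        minima.append((float(bs[i]), float(s[i])))
    return minima


def wy_fit(
    inp: RegressionInput,
    *,
    init: float | str = "wls",
    select: str = "global",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
) -> RegressionFit:
    """Fit the errors-in-both-variables line to a :class:`RegressionInput`.

    Parameters
    ----------
    init:
        Starting slope for ``select="init"``: either the string ``"wls"``
        (weighted least squares of y on x, weights 1/sy^2) or a number.
    select:
        ``"init"``, ``"global"`` or ``"positive"`` (see module docstring).
    """
    x, y, sx, sy = inp.x, inp.y, inp.sx, inp.sy
    if select == "init":
        b0 = wls_slope(x, y, sy) if init == "wls" else float(init)
        b, n_iter, converged = _york_iterate(x, y, sx, sy, b0, tol, max_iter)
        selection = "init"
    elif select in ("global", "positive"):
        minima = _stationary_minima(x, y, sx, sy)
        chosen = None
        selection = select
        if select == "positive":
            positive = [m for m in minima if m[0] > 0]
            if positive:
                chosen = min(positive, key=lambda m: m[1])
            else:
                selection = "global_fallback"
        if chosen is None:
            chosen = min(minima, key=lambda m: m[1])
        b, n_iter, converged = chosen[0], 0, True
    else:
        raise ValueError(f"unknown select mode {select!r}")

    ev = _york_eval(x, y, sx, sy, b)
    se_slope = ev["se_slope_raw"] * ev["scale"]
    se_intercept = ev["se_intercept_raw"] * ev["scale"]
    z = b / se_slope if se_slope > 0 else float("nan")
    p = float(stats.norm.sf(z))
    return RegressionFit(
        slope=float(b),
        intercept=ev["intercept"],
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        se_slope_raw=ev["se_slope_raw"],
        se_intercept_raw=ev["se_intercept_raw"],
        scale=ev["scale"],
        objective=ev["objective"],
        z=float(z),
        p_one_sided=p,
        alpha=alpha,
        n_points=inp.n_points,
        n_iter=n_iter,
        converged=converged,
        selection=selection,
        endpoint=inp.endpoint,
    )


def wald_one_sided(
    fit: RegressionFit,
    critical: float = ONE_SIDED_CRITICAL,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[bool, float]:
    """Upper-tail Wald test of slope > 0; returns (reject at alpha, p).

    ``critical`` is the uncorrected screening cut-off on z (1.64 for a
    one-sided 0.05 test); the decision itself is taken at the
    multiplicity-corrected ``alpha`` on the normal upper-tail p-value.
    A z below ``critical`` can never reject since alpha <= 0.05.
    """
    if not fit.se_slope > 0:
        raise ValueError("slope standard error must be positive")
    z = fit.slope / fit.se_slope
    p = float(stats.norm.sf(z))
    reject = (z > critical) and (p < alpha)
    return reject, p


def predict_rct_effect(fit: RegressionFit, x_craving: float) -> float:
    """Clinical-trial effect size predicted from a cue-craving effect size."""
    return fit.intercept + fit.slope * np.asarray(x_craving, dtype=float)
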