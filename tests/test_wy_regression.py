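import numpy as np
import pytest
from scipy import optimize, stats

from cuemeta import (
    RegressionInput,
    predict_rct_effect,
    wald_one_sided,
    wy_fit,
    york_objective,
)
from conftest import random_regression_instance


def brute_force_fit(inp, n_starts=24):
    """Independent oracle: minimize the full two-parameter objective
    sum((y - a - b x)^2 / (sy^2 + b^2 sx^2)) by quasi-Newton descent from a
    fan of slope directions, keeping the best optimum found."""

    def objective(theta):
        a, b = theta
        return float(
            np.sum((inp.y - a - b * inp.x) ** 2 / (inp.sy**2 + b**2 * inp.sx**2))
        )

    best = None
    for ang in np.linspace(-np.pi / 2 + 0.05, np.pi / 2 - 0.05, n_starts):
        b0 = np.tan(ang)
        a0 = np.mean(inp.y - b0 * inp.x)
        res = optimize.minimize(objective, [a0, b0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[0], best.x[1], best.fun


class TestOracleAgreement:
    def test_global_fit_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            inp = random_regression_instance(rng, int(rng.integers(4, 9)))
            fit = wy_fit(inp)  # global selection
            a_bf, b_bf, s_bf = brute_force_fit(inp)
            assert fit.slope == pytest.approx(b_bf, abs=1e-6)
            assert fit.intercept == pytest.approx(a_bf, abs=1e-6)
            assert fit.objective == pytest.approx(s_bf, abs=1e-8)

    def test_equal_errors_match_bruteforce(self):
        # isotropic per-point weights: the fit is the weighted orthogonal line
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, 7)
        y = 0.8 * x + rng.normal(0, 0.2, 7)
        s = np.full(7, 0.15)
        inp = RegressionInput(x=x, y=y, sx=s, sy=s)
        fit = wy_fit(inp)
        _, b_bf, _ = brute_force_fit(inp)
        assert fit.slope == pytest.approx(b_bf, abs=1e-6)


class TestLimitsAndInvariances:
    def test_reduces_to_weighted_ols_as_x_errors_vanish(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, 8)
        y = 1.3 * x - 0.2 + rng.normal(0, 0.2, 8)
        sy = rng.uniform(0.1, 0.3, 8)
        inp = RegressionInput(x=x, y=y, sx=np.full(8, 1e-8), sy=sy)
        fit = wy_fit(inp, select="init")
        w = 1 / sy**2
        xm, ym = (w * x).sum() / w.sum(), (w * y).sum() / w.sum()
        b_wls = (w * (x - xm) * (y - ym)).sum() / (w * (x - xm) ** 2).sum()
        assert fit.slope == pytest.approx(b_wls, abs=1e-6)

    def test_scale_equivariance_in_y(self):
        rng = np.random.default_rng(13)
        inp = random_regression_instance(rng, 7)
        c = 3.7
        scaled = RegressionInput(x=inp.x, y=c * inp.y, sx=inp.sx, sy=c * inp.sy)
        f1, f2 = wy_fit(inp), wy_fit(scaled)
        assert f2.slope == pytest.approx(c * f1.slope, rel=1e-8)
        assert f2.se_slope == pytest.approx(c * f1.se_slope, rel=1e-6)
        assert f2.z == pytest.approx(f1.z, rel=1e-6)
        assert f2.p_one_sided == pytest.approx(f1.p_one_sided, rel=1e-6)

    def test_exact_line_recovered(self):
        x = np.array([-1.0, -0.3, 0.2, 0.9, 1.5])
        inp = RegressionInput(x=x, y=2 * x, sx=np.full(5, 0.1), sy=np.full(5, 0.1))
        fit = wy_fit(inp)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert predict_rct_effect(fit, 0.4) == pytest.approx(0.8, abs=1e-8)

    def test_line_passes_through_weighted_centroid(self):
        rng = np.random.default_rng(17)
        inp = random_regression_instance(rng, 6)
        fit = wy_fit(inp)
        b = fit.slope
        w = 1 / (inp.sy**2 + b**2 * inp.sx**2)
        xc = (w * inp.x).sum() / w.sum()
        yc = (w * inp.y).sum() / w.sum()
        assert predict_rct_effect(fit, xc) == pytest.approx(yc, abs=1e-8)


class TestInference:
    @pytest.mark.parametrize(
        "slope, se, p_expected",
        [(0.253, 0.189, 0.090), (0.829, 0.747, 0.133)],
    )
    def test_one_sided_p_values(self, slope, se, p_expected):
        p = float(stats.norm.sf(slope / se))
        assert p == pytest.approx(p_expected, abs=0.001)
        assert p > 0.025  # not significant at the corrected level

    def test_null_slope_gives_half(self, heavy_input):
        fit = wy_fit(heavy_input, select="positive")
        fit.slope = 0.0
        reject, p = wald_one_sided(fit)
        assert p == pytest.approx(0.5)
        assert not reject

    def test_rejection_requires_corrected_alpha(self, heavy_input):
        fit = wy_fit(heavy_input, select="positive")
        reject, p = wald_one_sided(fit)
        assert not reject and 0.05 < p < 0.15


class TestSelectionModes:
    def test_profile_objective_matches_reported(self, heavy_input):
        fit = wy_fit(heavy_input, select="positive")
        s, a = york_objective(fit.slope, heavy_input.x, heavy_input.y,
                              heavy_input.sx, heavy_input.sy)
        assert s == pytest.approx(fit.objective, rel=1e-10)
        assert a == pytest.approx(fit.intercept, rel=1e-8)

    def test_positive_branch_differs_from_global_on_reference_data(
        self, heavy_input
    ):
        # the reference dataset's objective is bimodal with minima of
        # opposite sign; the analysis tracks the positive branch
        pos = wy_fit(heavy_input, select="positive")
        glob = wy_fit(heavy_input, select="global")
        assert pos.slope > 0 > glob.slope
        assert glob.objective < pos.objective

    def test_positive_falls_back_to_global_when_no_positive_minimum(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        inp = RegressionInput(x=x, y=-1.5 * x, sx=np.full(4, 0.1),
                              sy=np.full(4, 0.1))
        fit = wy_fit(inp, select="positive")
        assert fit.selection == "global_fallback"
        assert fit.slope == pytest.approx(-1.5, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            RegressionInput(x=[0, 1], y=[0, 1], sx=[0.1, 0.1], sy=[0.1, 0.1])

    def test_nonpositive_errors_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RegressionInput(x=[0, 1, 2], y=[0, 1, 2], sx=[0.1, 0.0, 0.1],
                            sy=[0.1, 0.1, 0.1])
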