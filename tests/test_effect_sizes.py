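import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuemeta import (
    StudyRecord,
    apply_sign_convention,
    effect_size_variance,
    effects_frame,
    hedges_g,
    map_to_endpoint,
    small_sample_correction,
    study_effect_size,
)


def make_record(**overrides) -> StudyRecord:
    base = dict(
        study_id="s", medication="m", paradigm="rct", outcome="drinks_per_week",
        design="parallel", n_med=20, mean_med=8.0, sd_med=2.0,
        n_ctrl=20, mean_ctrl=10.0, sd_ctrl=2.0,
    )
    base.update(overrides)
    return StudyRecord(**base)


class TestHedgesG:
    def test_hand_computed_value(self):
        # (8 - 10) / pooled SD 2 with equal arms
        assert hedges_g(make_record()) == pytest.approx(-1.0)

    def test_identical_means_give_zero(self):
        assert hedges_g(make_record(mean_med=5.0, mean_ctrl=5.0)) == 0.0

    def test_antisymmetry_under_arm_swap(self):
        rec = make_record(n_med=12, mean_med=3.0, sd_med=1.5, n_ctrl=30,
                          mean_ctrl=4.2, sd_ctrl=2.5)
        swapped = make_record(n_med=30, mean_med=4.2, sd_med=2.5, n_ctrl=12,
                              mean_ctrl=3.0, sd_ctrl=1.5)
        assert hedges_g(swapped) == pytest.approx(-hedges_g(rec))

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_scale_invariance(self, c):
        rec = make_record()
        scaled = make_record(mean_med=8.0 * c, mean_ctrl=10.0 * c,
                             sd_med=2.0 * c, sd_ctrl=2.0 * c)
        assert hedges_g(scaled) == pytest.approx(hedges_g(rec), rel=1e-9)

    def test_degenerate_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            make_record(sd_med=0.0, sd_ctrl=0.0)


class TestSmallSampleCorrection:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [(20, 20, 1 - 3 / 151), (2, 2, 1 - 3 / 7), (100, 100, 1 - 3 / 791)],
    )
    def test_hand_computed_values(self, n1, n2, expected):
        assert small_sample_correction(n1, n2) == pytest.approx(expected)

    def test_monotone_toward_one(self):
        values = [small_sample_correction(n, n) for n in (2, 5, 20, 200, 2000)]
        assert values == sorted(values)
        assert 0 < values[0] < values[-1] < 1

    def test_too_small_total_rejected(self):
        with pytest.raises(ValueError):
            small_sample_correction(1, 2)


class TestVariance:
    def test_null_effect_value(self):
        assert effect_size_variance(0.0, 20, 20) == pytest.approx(0.1)

    def test_increases_with_magnitude(self):
        assert effect_size_variance(0.5, 20, 20) > effect_size_variance(0.1, 20, 20)

    def test_halves_when_arms_double_at_null(self):
        assert effect_size_variance(0.0, 40, 40) == pytest.approx(
            effect_size_variance(0.0, 20, 20) / 2
        )


class TestSignsAndEndpoints:
    def test_pct_days_abstinent_flipped(self):
        assert apply_sign_convention(0.3, "pct_days_abstinent") == pytest.approx(-0.3)

    def test_other_outcomes_identity(self):
        assert apply_sign_convention(0.3, "pct_heavy_days") == 0.3
        assert apply_sign_convention(0.0, "drinks_per_day") == 0.0

    def test_flip_is_involution(self):
        d = 0.42
        once = apply_sign_convention(d, "pct_days_abstinent")
        assert apply_sign_convention(once, "pct_days_abstinent") == pytest.approx(d)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            apply_sign_convention(0.1, "nonsense")
        with pytest.raises(ValueError, match="unknown outcome"):
            map_to_endpoint("nonsense")

    @pytest.mark.parametrize(
        "outcome, endpoint",
        [
            ("drinks_per_week", "heavy_drinking"),
            ("drinks_per_day", "heavy_drinking"),
            ("drinks_per_drinking_day", "heavy_drinking"),
            ("pct_heavy_days", "heavy_drinking"),
            ("return_heavy_drinking", "heavy_drinking"),
            ("return_any_drinking", "abstinence"),
            ("pct_days_abstinent", "abstinence"),
            ("cue_craving", "cue_craving"),
        ],
    )
    def test_endpoint_amalgamation(self, outcome, endpoint):
        assert map_to_endpoint(outcome) == endpoint


class TestStudyEffectSize:
    def test_correction_shrinks_but_keeps_sign(self):
        rec = make_record()
        es = study_effect_size(rec)
        g = hedges_g(rec)
        assert math.copysign(1, es.value) == math.copysign(1, g)
        assert abs(es.value) < abs(g)

    def test_abstinence_outcome_is_flagged_and_flipped(self):
        rec = make_record(outcome="pct_days_abstinent", mean_med=10.0,
                          mean_ctrl=8.0)
        es = study_effect_size(rec)
        # medication arm more abstinent => effect favours medication => negative
        assert es.value < 0
        assert es.sign_flipped
        assert es.endpoint == "abstinence"

    def test_effects_frame_schema_and_crossover_flag(self):
        recs = [make_record(), make_record(study_id="s2", design="crossover")]
        frame = effects_frame(recs)
        assert list(frame["crossover"]) == [False, True]
        assert set(frame.columns) >= {
            "medication", "endpoint", "outcome", "study_id", "d", "variance",
            "sign_flipped",
        }
        assert (frame["variance"] > 0).all()

    def test_invalid_arm_size_rejected(self):
        with pytest.raises(ValueError):
            make_record(n_med=1)
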