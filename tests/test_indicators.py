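import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vectorcycle import (
    BloodMealCounts,
    SurveyData,
    ValidationError,
    exposure_distribution,
    human_blood_index,
    indoor_resting_fraction,
    residual_outdoor_fraction,
)
from vectorcycle.indicators import livestock_meal_fraction

from oracles import wilson_interval


def survey_from_arrays(b_in, b_out, h_in, h_bed):
    return SurveyData(
        pd.DataFrame(
            {
                "hour": np.arange(24),
                "bite_rate_indoor": b_in,
                "bite_rate_outdoor": b_out,
                "frac_humans_indoor": h_in,
                "frac_humans_in_bed": h_bed,
            }
        )
    )


class TestHumanBloodIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"human": 50, "cattle": 50}, 0.5),
            ({"human": 0, "cattle": 20}, 0.0),
            ({"human": 40, "cattle": 0}, 1.0),
        ],
    )
    def test_point_estimate(self, counts, expected):
        est = human_blood_index(BloodMealCounts(counts))
        assert est.estimate == pytest.approx(expected)
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_boundary_interval_starts_at_zero(self):
        est = human_blood_index(BloodMealCounts({"human": 0, "cattle": 20}))
        assert est.ci_low == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k, n", [(30, 40), (1, 50), (49, 50), (12, 40)])
    def test_interval_matches_closed_form_wilson(self, k, n):
        est = human_blood_index(
            BloodMealCounts({"human": k, "cattle": n - k}), conf=0.95
        )
        low, high = wilson_interval(k, n, 0.95)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValidationError):
            human_blood_index(BloodMealCounts({"human": 0, "cattle": 0}))

    def test_mixed_meals_count_half_to_each_host(self):
        est = human_blood_index(
            BloodMealCounts({"human": 10, "cattle": 10, "human+cattle": 10})
        )
        assert est.estimate == pytest.approx(0.5)

    def test_livestock_fraction_ignores_wild_hosts(self):
        counts = BloodMealCounts({"human": 10, "cattle": 20, "goat": 10, "other": 10})
        assert livestock_meal_fraction(counts).estimate == pytest.approx(0.6)


class TestExposureDistribution:
    def test_symmetric_survey_splits_evenly(self, uniform_survey):
        dist = exposure_distribution(uniform_survey)
        assert dist.pi_indoor == pytest.approx(0.5, abs=1e-12)
        assert dist.pi_in_bed == pytest.approx(0.5, abs=1e-12)

    def test_all_biting_while_indoors(self):
        h_in = np.zeros(24)
        h_in[20:] = 1.0
        b_in = np.zeros(24)
        b_in[20:] = 2.0
        survey = survey_from_arrays(b_in, np.zeros(24), h_in, np.zeros(24))
        assert exposure_distribution(survey).pi_indoor == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    def test_matches_per_hour_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        b_in = rng.gamma(2.0, 1.0, 24)
        b_out = rng.gamma(2.0, 1.0, 24)
        h_in = rng.uniform(0, 1, 24)
        h_bed = h_in * rng.uniform(0, 1, 24)
        survey = survey_from_arrays(b_in, b_out, h_in, h_bed)
        dist = exposure_distribution(survey)
        num = den = 0.0
        for t in range(24):
            num += b_in[t] * h_in[t]
            den += b_in[t] * h_in[t] + b_out[t] * (1.0 - h_in[t])
        assert dist.pi_indoor == pytest.approx(num / den, abs=1e-12)

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_rescaling_biting_rates(self, scale):
        rng = np.random.default_rng(1)
        b_in = rng.gamma(2.0, 1.0, 24)
        b_out = rng.gamma(2.0, 1.0, 24)
        h_in = rng.uniform(0, 1, 24)
        base = exposure_distribution(survey_from_arrays(b_in, b_out, h_in, 0 * h_in))
        scaled = exposure_distribution(
            survey_from_arrays(scale * b_in, scale * b_out, h_in, 0 * h_in)
        )
        assert scaled.pi_indoor == pytest.approx(base.pi_indoor, abs=1e-12)

    def test_all_zero_exposure_is_an_error(self):
        survey = survey_from_arrays(np.zeros(24), np.zeros(24), np.full(24, 0.5), np.zeros(24))
        with pytest.raises(ValidationError):
            exposure_distribution(survey)

    def test_in_bed_exceeding_indoor_rejected(self):
        with pytest.raises(ValidationError):
            survey_from_arrays(np.ones(24), np.ones(24), np.full(24, 0.3), np.full(24, 0.5))


class TestResidualOutdoorFraction:
    def test_no_screening_equals_outdoor_proportion(self, uniform_survey):
        dist = exposure_distribution(uniform_survey)
        assert residual_outdoor_fraction(uniform_survey, 0.0) == pytest.approx(
            1.0 - dist.pi_indoor, abs=1e-12
        )

    def test_ninety_percent_screening_closed_form(self):
        # indoor exposure 9x the outdoor exposure, 90% screening:
        # residual outdoor share = 1 / (1 + 0.9)
        h_in = np.full(24, 0.9)
        survey = survey_from_arrays(np.ones(24), np.ones(24), h_in, np.zeros(24))
        assert residual_outdoor_fraction(survey, 0.9) == pytest.approx(
            1.0 / 1.9, abs=1e-12
        )

    def test_perfect_screening_pushes_all_exposure_outdoors(self, uniform_survey):
        assert residual_outdoor_fraction(uniform_survey, 1.0) == pytest.approx(1.0)

    @given(e1=st.floats(0.0, 1.0), e2=st.floats(0.0, 1.0))
    def test_monotone_in_efficacy(self, e1, e2):
        survey = survey_from_arrays(
            np.ones(24), np.ones(24), np.full(24, 0.5), np.full(24, 0.25)
        )
        lo, hi = sorted((e1, e2))
        assert residual_outdoor_fraction(survey, hi) >= residual_outdoor_fraction(
            survey, lo
        )


class TestIndoorRestingFraction:
    @pytest.mark.parametrize(
        "indoor, outdoor, expected", [(25, 25, 0.5), (0, 40, 0.0), (12, 28, 0.3)]
    )
    def test_point_estimates(self, indoor, outdoor, expected):
        est = indoor_resting_fraction(indoor, outdoor)
        assert est.estimate == pytest.approx(expected)

    def test_interval_matches_closed_form(self):
        est = indoor_resting_fraction(12, 28, conf=0.95)
        low, high = wilson_interval(12, 40, 0.95)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    def test_method_tag_flags_the_approximation(self):
        assert "uncorrected" in indoor_resting_fraction(5, 5).method

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValidationError):
            indoor_resting_fraction(0, 0)
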