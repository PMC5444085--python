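import math

import pytest
from hypothesis import given, strategies as st

from vectorcycle import (
    BehaviourProfile,
    Compartment,
    DEFAULT_NET_BLOCK,
    Intervention,
    TotalBlockadeError,
    ValidationError,
    expected_encounters,
    population_coverage,
    single_cycle,
)

from oracles import mc_se, simulate_cycle

fractions = st.floats(0.0, 1.0, allow_nan=False)


def make_profile(q, pi, pb, fl=0.5, rest=0.5, sugar=0.0):
    return BehaviourProfile(q, pi, pb, fl, rest, sugar)


class TestExpectedEncounters:
    @pytest.mark.parametrize(
        "u, b, expected",
        [
            (0.8, 0.625, 2.0),      # 80% net usage doubles house entries
            (0.0, 0.9, 1.0),        # no coverage: one encounter suffices
            (0.8, 1.0, 5.0),        # 1 / (1 - 0.8)
        ],
    )
    def test_closed_form(self, u, b, expected):
        m = expected_encounters(u, b)
        assert m.e_expected == pytest.approx(expected, abs=1e-12)
        assert m.z_relative == pytest.approx(1.0 - u * b, abs=1e-12)

    def test_default_block_is_calibrated_for_doubling(self):
        assert expected_encounters(0.8).e_expected == pytest.approx(2.0)
        assert DEFAULT_NET_BLOCK == 0.625

    def test_total_blockade_raises(self):
        with pytest.raises(TotalBlockadeError):
            expected_encounters(1.0, 1.0)

    @given(u=st.floats(0.01, 0.95), b=st.floats(0.01, 0.95))
    def test_strictly_increasing_in_u_and_b(self, u, b):
        e = expected_encounters(u, b).e_expected
        assert expected_encounters(min(u + 0.01, 0.99), b).e_expected > e
        assert expected_encounters(u, min(b + 0.01, 0.99)).e_expected > e

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            expected_encounters(1.5, 0.5)


class TestPopulationCoverage:
    def test_full_coverage_limit_equals_pi_indoor(self):
        p = make_profile(1.0, 0.9, 1.0)
        assert population_coverage(1.0, p, e=1.0) == pytest.approx(0.9)

    def test_zero_coverage_is_zero(self, arabiensis_profile):
        assert population_coverage(0.0, arabiensis_profile, e=3.7) == 0.0

    def test_two_entries_closed_form(self):
        p = make_profile(1.0, 0.9, 1.0)
        assert population_coverage(0.5, p, e=2.0) == pytest.approx(
            1.0 - (1.0 - 0.45) ** 2
        )

    @given(
        c=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
        pi=st.floats(0.0, 1.0),
        e=st.floats(1.0, 5.0),
    )
    def test_simple_product_at_single_entry(self, c, q, pi, e):
        p = make_profile(q, pi, 0.5)
        assert population_coverage(c, p, e=1.0) == pytest.approx(
            q * pi * c, abs=1e-12
        )
        # monotone non-decreasing in coverage and in entries
        assert population_coverage(min(c + 0.05, 1.0), p, e=e) >= population_coverage(
            c, p, e=e
        ) - 1e-12
        assert population_coverage(c, p, e=e + 0.5) >= population_coverage(
            c, p, e=e
        ) - 1e-12

    def test_rejects_entries_below_one(self, arabiensis_profile):
        with pytest.raises(ValidationError):
            population_coverage(0.5, arabiensis_profile, e=0.5)


class TestProfileAndIntervention:
    def test_attempt_weights_sum_to_one(self, arabiensis_profile):
        w = arabiensis_profile.attempt_weights()
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in w.values())

    @given(q=fractions, pi=fractions, pb=fractions, fl=fractions)
    def test_weights_sum_to_one_everywhere(self, q, pi, pb, fl):
        w = make_profile(q, pi, pb, fl).attempt_weights()
        assert math.fsum(w.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_out_of_range_fraction(self):
        with pytest.raises(ValidationError):
            make_profile(1.2, 0.5, 0.5)

    def test_rejects_prekill_plus_block_above_one(self):
        with pytest.raises(ValidationError):
            Intervention(kind="LLIN", coverage=0.5, pre_kill=0.7, block=0.7)

    def test_rejects_targets_inconsistent_with_kind(self):
        with pytest.raises(ValidationError):
            Intervention(
                kind="LLIN",
                coverage=0.5,
                targets=frozenset({Compartment.LIVESTOCK}),
            )

    def test_default_targets_from_kind(self):
        iv = Intervention(kind="EMANATOR", coverage=0.5, block=0.3)
        assert iv.targets == frozenset({Compartment.HUMAN_OUTDOOR})


class TestSingleCycle:
    def test_no_interventions_is_baseline(self, arabiensis_profile):
        out = single_cycle(arabiensis_profile, [])
        assert out.p_pre_death == 0.0
        assert out.e_expected == 1.0
        assert out.p_cycle_survival == 1.0
        weights = arabiensis_profile.attempt_weights()
        for j, w in weights.items():
            assert out.p_fed[j] == pytest.approx(w, abs=1e-12)

    def test_total_blockade_raises(self):
        p = make_profile(1.0, 1.0, 1.0)
        with pytest.raises(TotalBlockadeError):
            single_cycle(p, [Intervention(kind="LLIN", coverage=1.0, block=1.0)])

    @given(
        q=fractions,
        pi=fractions,
        pb=fractions,
        fl=fractions,
        cov=st.floats(0.0, 0.9),
        pk=st.floats(0.0, 0.5),
        blk=st.floats(0.0, 0.5),
    )
    def test_conservation_of_fate_probability(self, q, pi, pb, fl, cov, pk, blk):
        out = single_cycle(
            make_profile(q, pi, pb, fl),
            [Intervention(kind="LLIN", coverage=cov, pre_kill=pk, block=blk)],
        )
        assert out.p_pre_death + math.fsum(out.p_fed.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_monte_carlo_oracle(self):
        profile = make_profile(0.5, 0.9, 1.0, fl=1.0)
        stack = [Intervention(kind="LLIN", coverage=0.8, pre_kill=0.2, block=0.5)]
        out = single_cycle(profile, stack)
        sim = simulate_cycle(profile, stack, n=200_000, seed=42)
        n = sim["n"]
        assert abs(out.p_pre_death - sim["p_pre_death"]) < 3 * mc_se(
            out.p_pre_death, n
        )
        for j in out.p_fed:
            assert abs(out.p_fed[j] - sim["p_fed"][j]) < 3 * mc_se(out.p_fed[j], n)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_matches_oracle_with_layered_and_post_bite_hazards(self, seed):
        profile = make_profile(0.6, 0.8, 0.7, fl=0.8, rest=0.5, sugar=0.4)
        stack = [
            Intervention(kind="LLIN", coverage=0.7, pre_kill=0.15, block=0.5),
            Intervention(kind="SCREENING", coverage=0.4, block=0.8),
            Intervention(kind="IRS", coverage=0.6, post_kill=0.8),
            Intervention(kind="LIVESTOCK_INSECTICIDE", coverage=0.5, post_kill=0.7),
            Intervention(kind="SUGAR_BAIT", coverage=0.3, post_kill=0.9),
        ]
        out = single_cycle(profile, stack)
        sim = simulate_cycle(profile, stack, n=150_000, seed=seed)
        n = sim["n"]
        assert abs(out.p_pre_death - sim["p_pre_death"]) < 3 * mc_se(
            out.p_pre_death, n
        )
        for j in out.p_fed:
            assert abs(out.p_fed[j] - sim["p_fed"][j]) < 3 * mc_se(out.p_fed[j], n)
        assert abs(out.p_post_death - sim["p_post_death"]) < 3 * mc_se(
            out.p_post_death, n
        )
        assert abs(out.p_cycle_survival - sim["p_cycle_survival"]) < 3 * mc_se(
            out.p_cycle_survival, n
        )
        assert abs(out.e_expected - sim["mean_attempts"]) < 0.02

    def test_coverage_reported_per_intervention(self, arabiensis_profile, llin):
        out = single_cycle(arabiensis_profile, [llin])
        assert len(out.c_m) == 1
        assert 0.0 <= out.c_m[0] <= 1.0
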