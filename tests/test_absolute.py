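import numpy as np
import pytest

from absrisk import (
    BaselineRisk,
    RelativeEffect,
    compute_absolute_effect,
    microsim_rd,
    risk_under_treatment,
    round_per1000,
    substitution_rd,
)


def log_symmetric(measure, point, sigma_z):
    """Effect whose CI is exp(log point +/- sigma_z), i.e. exactly the
    interval the fitted lognormal reproduces."""
    return RelativeEffect(measure, point,
                          point * np.exp(-sigma_z), point * np.exp(sigma_z))


class TestRiskUnderTreatment:
    @pytest.mark.parametrize("measure", ["RR", "OR", "HR"])
    def test_null_effect_is_identity(self, measure):
        assert risk_under_treatment(0.5, 1.0, measure) == pytest.approx(0.5)

    def test_zero_baseline_stays_zero(self):
        assert risk_under_treatment(0.0, 2.0, "HR") == 0.0
        assert risk_under_treatment(0.0, 2.0, "RR") == 0.0

    def test_rr_truncates_at_one(self):
        assert risk_under_treatment(0.8, 2.0, "RR") == 1.0

    def test_odds_ratio_inverts(self):
        out = risk_under_treatment(0.2, 1.5, "OR")
        assert out == pytest.approx(0.272727, abs=1e-5)
        odds_ratio = (out / (1 - out)) / (0.2 / 0.8)
        assert odds_ratio == pytest.approx(1.5, abs=1e-12)

    def test_hazard_ratio_acts_on_survival(self):
        out = risk_under_treatment(0.3, 2.0, "HR")
        assert out == pytest.approx(1 - 0.7**2, abs=1e-12)


class TestSubstitution:
    def test_headline_rr_example(self):
        """BR 0.2 with RR 1.5 (1.2-1.8) gives RD 100 (40-160) per 1,000."""
        point, lo, hi = substitution_rd(
            BaselineRisk(0.2, 0.2, 0.2), RelativeEffect("RR", 1.5, 1.2, 1.8))
        assert point == pytest.approx(0.10)
        assert lo == pytest.approx(0.04)
        assert hi == pytest.approx(0.16)

    def test_null_effect_gives_zero_rd(self):
        point, lo, hi = substitution_rd(
            BaselineRisk(0.3, 0.25, 0.35), RelativeEffect("RR", 1.0, 1.0, 1.0))
        assert (point, lo, hi) == (0.0, 0.0, 0.0)

    def test_odds_ratio_bounds_by_hand(self):
        br = BaselineRisk(0.1, 0.1, 0.1)
        point, lo, hi = substitution_rd(br, RelativeEffect("OR", 2.0, 1.5, 3.0))
        # odds 1/9 scaled by the OR, back to a probability, minus 0.1
        for got, odds_ratio in ((point, 2.0), (lo, 1.5), (hi, 3.0)):
            odds = odds_ratio * (0.1 / 0.9)
            assert got == pytest.approx(odds / (1 + odds) - 0.1, abs=1e-12)

    def test_bounds_stay_ordered_for_protective_effects(self):
        _, lo, hi = substitution_rd(
            BaselineRisk(0.4, 0.4, 0.4), RelativeEffect("RR", 0.5, 0.25, 1.0))
        assert lo <= hi < 0.001


class TestRoundPer1000:
    @pytest.mark.parametrize("x,expected", [
        (0.16, 160), (0.04, 40), (0.1001, 101), (0.0, 0),
        (-0.0401, -41), (-0.16, -160), (0.0005, 1), (-0.0005, -1),
    ])
    def test_away_from_zero_with_float_guard(self, x, expected):
        assert round_per1000(x) == expected


class TestMicrosim:
    def test_rejects_too_few_draws(self):
        with pytest.raises(ValueError, match="n_draws"):
            microsim_rd(BaselineRisk(0.2, 0.2, 0.2),
                        RelativeEffect("RR", 1.5, 1.2, 1.8), n_draws=100, seed=0)

    def test_fully_degenerate_inputs_give_zero_width(self):
        m = microsim_rd(BaselineRisk(0.2, 0.2, 0.2),
                        RelativeEffect("RR", 1.5, 1.5, 1.5),
                        n_draws=10_000, seed=0)
        assert m.lower == m.upper == m.point == pytest.approx(0.10)

    @pytest.mark.parametrize("measure", ["RR", "OR", "HR"])
    def test_degenerate_br_recovers_substitution(self, measure):
        """With a fixed BR, the RD is a monotone transform of the effect, so
        microsim quantiles converge to the substitution bounds."""
        br = BaselineRisk(0.2, 0.2, 0.2)
        eff = log_symmetric(measure, 1.5, 0.3)
        m = microsim_rd(br, eff, n_draws=1_000_000, seed=11)
        _, s_lo, s_hi = substitution_rd(br, eff)
        assert m.lower == pytest.approx(s_lo, abs=0.002)
        assert m.upper == pytest.approx(s_hi, abs=0.002)

    def test_regression_against_high_precision_oracle(self):
        """Frozen from a 10^7-draw run of this generator chain."""
        m = microsim_rd(BaselineRisk(0.2, 0.15, 0.25),
                        RelativeEffect("RR", 1.5, 1.2, 1.8),
                        n_draws=10_000_000, seed=20240901)
        assert m.lower == pytest.approx(0.042977706589317426, rel=1e-12)
        assert m.upper == pytest.approx(0.17636881882500688, rel=1e-12)
        assert m.median == pytest.approx(0.09879186773908999, rel=1e-12)

    def test_br_uncertainty_widens_interval(self):
        br_wide = BaselineRisk(0.2, 0.15, 0.25)
        eff = log_symmetric("RR", 1.5, 0.2)
        m = microsim_rd(br_wide, eff, n_draws=1_000_000, seed=3)
        _, s_lo, s_hi = substitution_rd(br_wide, eff)
        assert (m.upper - m.lower) > (s_hi - s_lo)

    def test_monotone_expansion_over_widening_ladder(self):
        """Widening the BR CI never shrinks the microsim CI (paired seeds)."""
        eff = log_symmetric("RR", 1.5, 0.2)
        widths = [0.0, 0.02, 0.05, 0.10, 0.16]
        ci_widths = []
        for w in widths:
            br = BaselineRisk(0.2, 0.2 - w / 2, 0.2 + w / 2)
            m = microsim_rd(br, eff, n_draws=1_000_000, seed=77)
            ci_widths.append(m.upper - m.lower)
        mc_slack = 0.002
        assert all(b >= a - mc_slack for a, b in zip(ci_widths, ci_widths[1:]))

    def test_determinism_bit_identical(self):
        args = (BaselineRisk(0.2, 0.15, 0.25), log_symmetric("OR", 2.0, 0.25))
        m1 = microsim_rd(*args, n_draws=100_000, seed=5)
        m2 = microsim_rd(*args, n_draws=100_000, seed=5)
        assert m1 == m2


class TestComputeAbsoluteEffect:
    def test_widths_and_expansion_are_consistent(self):
        res = compute_absolute_effect(
            BaselineRisk(0.2, 0.15, 0.25), log_symmetric("RR", 1.5, 0.2),
            n_draws=200_000, seed=9)
        assert res.subst_width_per1000 == \
            res.subst_upper_per1000 - res.subst_lower_per1000
        assert res.micro_width_per1000 == \
            res.micro_upper_per1000 - res.micro_lower_per1000
        assert res.expansion_per1000 == \
            res.micro_width_per1000 - res.subst_width_per1000
        assert res.raw_subst_lower <= res.raw_rd_point <= res.raw_subst_upper

    def test_degenerate_inputs_give_zero_expansion(self):
        res = compute_absolute_effect(
            BaselineRisk(0.2, 0.2, 0.2), RelativeEffect("RR", 1.5, 1.5, 1.5),
            n_draws=10_000, seed=0)
        assert res.expansion_per1000 == 0
        assert res.rd_point_per1000 == 100

    def test_non_contraction_across_inputs(self):
        """Adding BR uncertainty should never shrink the CI beyond MC slack."""
        cases = [
            (BaselineRisk(0.1, 0.05, 0.15), log_symmetric("RR", 0.7, 0.3)),
            (BaselineRisk(0.3, 0.2, 0.4), log_symmetric("OR", 1.2, 0.15)),
            (BaselineRisk(0.05, 0.01, 0.12), log_symmetric("HR", 2.0, 0.4)),
        ]
        for br, eff in cases:
            res = compute_absolute_effect(br, eff, n_draws=1_000_000, seed=13)
            assert res.expansion_per1000 >= -2

    def test_frozen_full_record(self):
        res = compute_absolute_effect(
            BaselineRisk(0.2, 0.15, 0.25), RelativeEffect("RR", 1.5, 1.2, 1.8),
            n_draws=10_000_000, seed=20240901)
        assert res.rd_point_per1000 == 100
        assert (res.subst_lower_per1000, res.subst_upper_per1000) == (40, 160)
        assert (res.micro_lower_per1000, res.micro_upper_per1000) == (43, 177)
        assert res.expansion_per1000 == 14
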