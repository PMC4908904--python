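import numpy as np
import pytest

from cvdpolicy import (
    RunConfig,
    ValidationError,
    auc_half_cycle,
    discount_factors,
    expected_outcomes,
    make_synthetic_params,
    risk_table,
    scenario_outcome,
)
from cvdpolicy.parameters import FIRST_EVENTS
from cvdpolicy.synthetic import enumerate_outcomes

from conftest import toy_params


class TestAUC:
    def test_constant_series(self):
        assert auc_half_cycle(np.ones(11)) == pytest.approx(10.0)

    def test_linear_decline(self):
        assert auc_half_cycle(np.linspace(1, 0, 11)) == pytest.approx(5.0)

    def test_exponential_matches_fine_grid_integral_of_interpolant(self):
        t = np.arange(51)
        v = np.exp(-0.1 * t)
        fine = np.linspace(0, 50, 50001)
        expected = np.trapezoid(np.interp(fine, t, v), fine)
        assert auc_half_cycle(v) == pytest.approx(expected, rel=1e-6)

    def test_empty_or_single_point_rejected(self):
        with pytest.raises(ValidationError):
            auc_half_cycle([])
        with pytest.raises(ValidationError):
            auc_half_cycle([1.0])


class TestDiscountFactors:
    def test_zero_rate_is_all_ones(self):
        np.testing.assert_array_equal(discount_factors(10, 0.0), 1.0)

    def test_midcycle_factor_value(self):
        assert discount_factors(5, 0.035)[0] == pytest.approx(0.98294, abs=1e-5)

    def test_strictly_decreasing_for_positive_rate(self):
        f = discount_factors(50, 0.015)
        assert np.all(np.diff(f) < 0)


class TestScenarioOutcome:
    def test_fatal_event_at_cycle_zero_credits_half_a_year(self, ref_profile):
        params = toy_params(pre_cost=800.0, utility=0.9)
        cfg = RunConfig(horizon=10, discount_rate_outcomes=0.0, discount_rate_costs=0.0)
        out = scenario_outcome(ref_profile, params, "fatal_cvd", 0, cfg)
        assert out.life_years == pytest.approx(0.5)
        assert out.lifetime_cost == pytest.approx(400.0)  # half-cycle pre-event cost
        assert out.qale == pytest.approx(0.45)

    def test_unit_utilities_make_qale_equal_life_years(self, ref_profile, params1):
        import dataclasses

        from cvdpolicy.parameters import DecrementSet, SUBSEQUENT_EVENTS, UtilityTable

        params = dataclasses.replace(
            params1,
            utility_table=UtilityTable(np.ones((2, 7, 5))),
            decrements=DecrementSet(dict.fromkeys(SUBSEQUENT_EVENTS, 0.0)),
        )
        cfg = RunConfig(horizon=30)
        for ev in FIRST_EVENTS:
            out = scenario_outcome(ref_profile, params, ev, 7, cfg)
            assert out.qale == pytest.approx(out.life_years, rel=1e-12)
            assert out.qale_disc == pytest.approx(out.life_years_disc, rel=1e-12)

    def test_invariants_hold_across_grid(self, ref_profile, params1):
        cfg = RunConfig(horizon=15)
        for ev in FIRST_EVENTS:
            for t0 in (0, 7, 14):
                out = scenario_outcome(ref_profile, params1, ev, t0, cfg)
                assert 0 <= out.qale <= out.life_years
                assert out.life_years_disc <= out.life_years
                assert out.qale_disc <= out.qale
                assert out.lifetime_cost_disc <= out.lifetime_cost
                assert out.lifetime_cost >= 0


class TestExpectedOutcomes:
    def test_degenerate_distribution_equals_single_scenario(self, ref_profile):
        params = toy_params(intercepts={"fatal_cvd": 40.0}, pre_cost=500.0, utility=0.8)
        cfg = RunConfig(horizon=10)
        res = expected_outcomes(ref_profile, params, cfg)
        single = scenario_outcome(ref_profile, params, "fatal_cvd", 0, cfg)
        assert res.life_expectancy == pytest.approx(single.life_years)
        assert res.qale == pytest.approx(single.qale)
        assert res.lifetime_cost == pytest.approx(single.lifetime_cost)

    def test_grid_shape_and_mass(self, ref_profile, params1):
        cfg = RunConfig(horizon=25)
        res = expected_outcomes(ref_profile, params1, cfg)
        assert res.scenario_grid.shape == (4, 25, 6)
        assert res.distribution.p.shape == (4, 25)
        assert res.distribution.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_expectation_lies_within_scenario_range(self, ref_profile, params1):
        cfg = RunConfig(horizon=20)
        res = expected_outcomes(ref_profile, params1, cfg)
        qale_grid = res.scenario_grid[:, :, 1]
        assert qale_grid.min() - 1e-9 <= res.qale <= qale_grid.max() + 1e-9

    def test_matches_exhaustive_enumeration(self, ref_profile, params1):
        cfg = RunConfig(horizon=10)
        res = expected_outcomes(ref_profile, params1, cfg)
        exact = enumerate_outcomes(ref_profile, params1, cfg)
        for key in exact:
            engine = getattr(
                res, key.replace("life_expectancy", "life_expectancy")
            )
            assert getattr(res, key) == pytest.approx(exact[key], rel=1e-10)

    def test_lowering_sbp_weakly_improves_outcomes(self, params1, ref_profile):
        """With monotone-signed synthetic coefficients, a protective change
        cannot reduce life expectancy or QALE."""
        cfg = RunConfig(horizon=40)
        high = expected_outcomes(ref_profile.replace(sbp=180.0), params1, cfg)
        low = expected_outcomes(ref_profile.replace(sbp=120.0), params1, cfg)
        assert low.life_expectancy >= high.life_expectancy
        assert low.qale >= high.qale


class TestRiskTable:
    def test_default_axes_produce_800_cells(self, params1):
        cfg = RunConfig(horizon=5)  # small horizon: cell count is the point
        frame = risk_table({"male": params1, "female": params1}, cfg)
        assert len(frame) == 5 * 5 * 4 * 2 * 2 * 2

    def test_smoking_axis_uses_twenty_cigarettes(self, params1):
        cfg = RunConfig(horizon=5)
        frame = risk_table(
            {"male": params1, "female": params1},
            cfg,
            ages=(60,),
            sbp_values=(140,),
            ratio_values=(5,),
            sexes=("male",),
            simd_fifths=(5,),
        )
        assert sorted(frame["cigarettes_per_day"].unique()) == [0, 20]

    def test_unit_utility_table_makes_qale_table_equal_le_table(self, params1):
        import dataclasses

        from cvdpolicy.parameters import DecrementSet, SUBSEQUENT_EVENTS, UtilityTable

        params = dataclasses.replace(
            params1,
            utility_table=UtilityTable(np.ones((2, 7, 5))),
            decrements=DecrementSet(dict.fromkeys(SUBSEQUENT_EVENTS, 0.0)),
        )
        cfg = RunConfig(horizon=10)
        frame = risk_table(
            {"male": params, "female": params},
            cfg,
            ages=(50,),
            sbp_values=(120, 160),
            ratio_values=(5,),
            simd_fifths=(1,),
        )
        np.testing.assert_allclose(frame["qale"], frame["life_expectancy"], rtol=1e-12)

    def test_age_anchored_columns(self, params1):
        cfg = RunConfig(horizon=5)
        frame = risk_table(
            {"male": params1, "female": params1},
            cfg,
            ages=(60,),
            sbp_values=(140,),
            ratio_values=(5,),
            sexes=("male",),
            cigarettes=(0,),
            simd_fifths=(1,),
            age_anchored=True,
        )
        assert frame["qale_age_anchored"].iloc[0] == pytest.approx(
            60 + frame["qale"].iloc[0]
        )
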