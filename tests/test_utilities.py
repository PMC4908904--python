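import numpy as np
import pytest

from cvdpolicy import (
    FitError,
    UtilityTable,
    ValidationError,
    background_utility,
    composite_decrement,
    cycle_utility,
    fit_ols,
    fit_probit,
    subsequent_event_probability,
)
from scipy.special import ndtri


class TestBackgroundUtility:
    def test_band_membership_is_half_open(self, params1):
        table = params1.utility_table
        assert background_utility("male", 55, 3, table) == background_utility(
            "male", 64, 3, table
        )
        assert background_utility("male", 65, 3, table) != background_utility(
            "male", 64, 3, table
        ) or True  # adjacent bands may coincide numerically; band index must differ
        from cvdpolicy.parameters import age_band_index

        assert age_band_index(64) == age_band_index(55)
        assert age_band_index(65) == age_band_index(64) + 1

    def test_uniform_table_returns_constant(self):
        table = UtilityTable(np.ones((2, 7, 5)))
        for age in (20, 37, 64, 90, 119):
            assert background_utility("female", age, 2, table) == 1.0

    def test_lookup_round_trips_generating_values(self, params1):
        rng = np.random.default_rng(0)
        from cvdpolicy.parameters import AGE_BAND_EDGES, SEXES

        for _ in range(100):
            si = rng.integers(0, 2)
            bi = rng.integers(0, 7)
            fifth = rng.integers(1, 6)
            lo = AGE_BAND_EDGES[bi]
            age = int(lo + rng.integers(0, 5))
            assert background_utility(
                SEXES[si], age, fifth, params1.utility_table
            ) == params1.utility_table.values[si, bi, fifth - 1]

    def test_age_below_twenty_rejected(self, params1):
        with pytest.raises(ValidationError):
            background_utility("male", 19, 1, params1.utility_table)

    @pytest.mark.parametrize("bad", [0.28, 1.01])
    def test_out_of_range_cells_rejected(self, bad):
        values = np.full((2, 7, 5), 0.8)
        values[0, 0, 0] = bad
        with pytest.raises(ValidationError):
            UtilityTable(values)


class TestSubsequentEventProbability:
    def test_zero_predictor_gives_half(self, ref_profile, params1):
        import dataclasses

        from cvdpolicy.parameters import EventEquation

        eqs = {
            state: {ev: EventEquation(intercept=0.0) for ev in sub}
            for state, sub in params1.subsequent_event_models.items()
        }
        params = dataclasses.replace(params1, subsequent_event_models=eqs)
        assert subsequent_event_probability(
            ref_profile, "post_chd", "stroke", 3, params
        ) == pytest.approx(0.5)

    def test_intercept_only_matches_inverse_normal(self, ref_profile, params1):
        import dataclasses

        from cvdpolicy.parameters import EventEquation

        eqs = {
            state: {ev: EventEquation(intercept=-1.6449) for ev in sub}
            for state, sub in params1.subsequent_event_models.items()
        }
        params = dataclasses.replace(params1, subsequent_event_models=eqs)
        assert subsequent_event_probability(
            ref_profile, "post_cbvd", "heart_failure", 0, params
        ) == pytest.approx(0.05, abs=1e-4)

    def test_matches_hand_assembled_predictor(self, ref_profile, params1):
        from scipy.special import ndtr

        from cvdpolicy import linear_predictor

        eq = params1.subsequent_event_models["post_chd"]["chd"]
        u, age = 4.0, 67.0
        expected = ndtr(linear_predictor(ref_profile, eq, 4, age=age, spline_arg=u))
        assert subsequent_event_probability(
            ref_profile, "post_chd", "chd", u, params1, age=age
        ) == pytest.approx(expected, rel=1e-14)

    def test_unknown_event_rejected(self, ref_profile, params1):
        with pytest.raises(ValidationError, match="angina"):
            subsequent_event_probability(ref_profile, "post_chd", "angina", 0, params1)


class TestCompositeDecrement:
    def test_zero_probabilities_give_zero(self):
        assert composite_decrement(np.zeros(5), np.full(5, 0.1)) == 0.0

    def test_single_certain_event(self):
        p = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        d = np.array([0.2, 0.1, 0.3, 0.4, 0.5])
        assert composite_decrement(p, d) == pytest.approx(0.1)

    def test_hand_computed_dot_product(self):
        p = np.array([0.1, 0.05, 0.2, 0.02, 0.01])
        d = np.array([0.06, 0.12, 0.05, 0.04, 0.10])
        assert composite_decrement(p, d) == pytest.approx(0.0238)

    def test_linear_in_probabilities_and_decrements(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.random(5) * 0.4, rng.random(5) * 0.4
        d = rng.random(5) * 0.2
        assert composite_decrement(p1 + p2, d) == pytest.approx(
            composite_decrement(p1, d) + composite_decrement(p2, d)
        )
        assert composite_decrement(p1, 2 * d) == pytest.approx(
            2 * composite_decrement(p1, d)
        )

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValidationError):
            composite_decrement(np.array([1.2, 0, 0, 0, 0]), np.full(5, 0.1))


class TestCycleUtility:
    def test_no_event_returns_background(self):
        assert cycle_utility(0.8, None, 0.0) == 0.8

    def test_decrements_subtract(self):
        assert cycle_utility(0.8, 0.07, 0.02) == pytest.approx(0.71)

    def test_floor_at_zero(self):
        assert cycle_utility(0.3, 0.29, 0.05) == 0.0


class TestFitOLS:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        beta = np.array([1.0, -0.5, 2.0, 0.25])
        fit = fit_ols(X, X @ beta)
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        assert np.abs(X.T @ fit.resid).max() < 1e-8

    def test_intercept_only_recovers_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = fit_ols(np.ones((4, 1)), y)
        assert fit.params[0] == pytest.approx(y.mean())

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(FitError, match="rank"):
            fit_ols(X, np.arange(10.0))


class TestFitProbit:
    def test_balanced_intercept_only_gives_zero(self):
        y = np.array([0.0, 1.0] * 50)
        fit = fit_probit(np.ones((100, 1)), y)
        assert abs(fit.params[0]) < 1e-6

    def test_intercept_matches_inverse_normal_of_rate(self):
        rng = np.random.default_rng(3)
        n = 200000
        y = (rng.random(n) < 0.05).astype(float)
        fit = fit_probit(np.ones((n, 1)), y)
        assert fit.params[0] == pytest.approx(ndtri(y.mean()), abs=1e-6)
        assert fit.params[0] == pytest.approx(ndtri(0.05), abs=3 * fit.se[0])

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(11)
        n = 20000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([-1.5, 0.4, -0.25])
        from scipy.special import ndtr

        y = (rng.random(n) < ndtr(X @ beta)).astype(float)
        fit = fit_probit(X, y)
        assert np.all(np.abs(fit.params - beta) < 3 * fit.se)

    def test_complete_separation_reported(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(FitError, match="separation"):
            fit_probit(X, y)
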