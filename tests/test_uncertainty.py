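import numpy as np
import pytest

from cvdpolicy import (
    Intervention,
    RiskFactorChange,
    RunConfig,
    ValidationError,
    analysis_of_extremes,
    cholesky_factor,
    evaluate_intervention,
    one_way_sa,
    psa_draw,
    run_psa,
)


@pytest.fixture
def cfg():
    return RunConfig(horizon=20)


@pytest.fixture
def iv():
    return Intervention(
        changes={"sbp": RiskFactorChange("add", -20)}, one_off_cost=300.0
    )


class TestCholesky:
    def test_identity(self):
        np.testing.assert_array_equal(cholesky_factor(np.eye(3)), np.eye(3))

    def test_hand_factorization(self):
        L = cholesky_factor(np.array([[4.0, 2.0], [2.0, 3.0]]))
        np.testing.assert_allclose(L, [[2.0, 0.0], [1.0, np.sqrt(2.0)]])

    def test_random_psd_reconstructs(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(20, 25))
        vcov = A @ A.T
        L = cholesky_factor(vcov)
        assert np.abs(L @ L.T - vcov).max() < 1e-10

    def test_semidefinite_clipped_with_warning(self):
        v = np.ones((2, 2))  # rank 1, PSD
        with pytest.warns(UserWarning, match="clipped"):
            L = cholesky_factor(v)
        assert np.abs(L @ L.T - v).max() < 1e-6

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            cholesky_factor(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_indefinite_rejected(self):
        with pytest.raises(ValidationError, match="semi-definite"):
            cholesky_factor(np.array([[1.0, 0.0], [0.0, -1e-3]]))


class TestPSADraw:
    def test_zero_factor_returns_means(self):
        means = np.array([1.0, -2.0, 3.0])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(psa_draw(means, np.zeros((3, 3)), rng), means)

    def test_seeded_draws_are_reproducible(self):
        means = np.zeros(4)
        L = np.linalg.cholesky(np.eye(4) * 2.0)
        d1 = psa_draw(means, L, np.random.default_rng(9))
        d2 = psa_draw(means, L, np.random.default_rng(9))
        np.testing.assert_array_equal(d1, d2)

    def test_sample_covariance_converges(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 8))
        vcov = A @ A.T
        L = cholesky_factor(vcov)
        draws = np.array([psa_draw(np.zeros(5), L, rng) for _ in range(10000)])
        emp = np.cov(draws.T)
        frob = np.linalg.norm(emp - vcov) / np.linalg.norm(vcov)
        assert frob < 0.10


class TestRunPSA:
    def test_zero_vcov_gives_point_estimate_and_step_ceac(
        self, ref_profile, params1, cfg, iv
    ):
        import dataclasses

        frozen = dataclasses.replace(
            params1, vcov=np.zeros_like(np.asarray(params1.vcov))
        )
        draws, ceac = run_psa(
            ref_profile, iv, frozen, cfg, n_draws=8, seed=2,
            lambda_grid=np.linspace(0, 40000, 9),
        )
        point = evaluate_intervention(ref_profile, iv, params1, cfg)
        np.testing.assert_allclose(draws.delta_qale, point.delta_qale_disc)
        np.testing.assert_allclose(draws.delta_cost, point.delta_cost_disc)
        assert set(np.unique(ceac.probability)) <= {0.0, 1.0}  # step function

    def test_seeded_runs_bit_reproducible(self, ref_profile, params1, cfg, iv):
        a = run_psa(ref_profile, iv, params1, cfg, n_draws=20, seed=13)
        b = run_psa(ref_profile, iv, params1, cfg, n_draws=20, seed=13)
        np.testing.assert_array_equal(a[0].parameters, b[0].parameters)
        np.testing.assert_array_equal(a[0].delta_qale, b[0].delta_qale)
        np.testing.assert_array_equal(a[1].probability, b[1].probability)

    def test_ceac_monotone_when_all_draws_gain_qale(self, ref_profile, params1, cfg, iv):
        """With uncertainty confined to the cost parameters every draw keeps
        the same positive QALE gain, so the CEAC must be non-decreasing."""
        import dataclasses

        names = params1.parameter_ordering()
        keep = np.array([n.startswith("cost.") for n in names])
        vcov = np.asarray(params1.vcov).copy()
        vcov[~keep, :] = 0.0
        vcov[:, ~keep] = 0.0
        cost_only = dataclasses.replace(params1, vcov=vcov)
        draws, ceac = run_psa(ref_profile, iv, cost_only, cfg, n_draws=60, seed=13)
        assert np.all(draws.delta_qale > 0)
        assert np.all(np.diff(ceac.probability) >= 0)

    def test_ceac_at_zero_wtp_is_cost_saving_share(self, ref_profile, params1, cfg, iv):
        draws, ceac = run_psa(
            ref_profile, iv, params1, cfg, n_draws=40, seed=3,
            lambda_grid=np.array([0.0, 20000.0]),
        )
        assert ceac.probability[0] == pytest.approx((draws.delta_cost < 0).mean())

    def test_mean_delta_qale_near_deterministic_value(self, ref_profile, params1, cfg, iv):
        """CLT check under a linear-in-parameter setup: QALE is exactly
        linear in the decrements and utility cells (floor slack), so the PSA
        mean over those draws brackets the point estimate."""
        import dataclasses

        names = params1.parameter_ordering()
        keep = np.array([n.startswith(("decrement.", "utility.")) for n in names])
        vcov = np.asarray(params1.vcov).copy()
        vcov[~keep, :] = 0.0
        vcov[:, ~keep] = 0.0
        linearised = dataclasses.replace(params1, vcov=vcov)
        draws, _ = run_psa(ref_profile, iv, linearised, cfg, n_draws=200, seed=13)
        point = evaluate_intervention(ref_profile, iv, params1, cfg).delta_qale_disc
        se = draws.delta_qale.std(ddof=1) / np.sqrt(draws.delta_qale.size)
        assert abs(draws.delta_qale.mean() - point) < 3 * se + 1e-12


class TestAnalysisOfExtremes:
    def test_zero_vcov_collapses_all_three_cases(self, ref_profile, params1, cfg, iv):
        import dataclasses

        frozen = dataclasses.replace(
            params1, vcov=np.zeros_like(np.asarray(params1.vcov))
        )
        out = analysis_of_extremes(ref_profile, iv, frozen, cfg)
        assert (
            out["worst"].delta_qale_disc
            == out["expected"].delta_qale_disc
            == out["best"].delta_qale_disc
        )

    def test_ordering_best_expected_worst(self, ref_profile, params1, cfg, iv):
        names = [
            n
            for n in params1.parameter_ordering()
            if n.startswith(("decrement.", "event.nonfatal_chd.intercept"))
        ]
        out = analysis_of_extremes(
            ref_profile, iv, params1, cfg, parameters=names
        )
        assert out["best"].delta_qale_disc >= out["expected"].delta_qale_disc
        assert out["expected"].delta_qale_disc >= out["worst"].delta_qale_disc

    def test_single_parameter_matches_manual_runs(self, ref_profile, params1, cfg, iv):
        name = "event.nonfatal_chd.intercept"
        names = list(params1.parameter_ordering())
        i = names.index(name)
        out = analysis_of_extremes(ref_profile, iv, params1, cfg, parameters=[name])
        z = 1.959963984540054
        se = params1.standard_errors()[i]
        manual = {}
        for sign in (-1, 1):
            vec = params1.parameter_vector()
            vec[i] += sign * z * se
            manual[sign] = evaluate_intervention(
                ref_profile, iv, params1.with_parameter_vector(vec), cfg
            ).delta_qale_disc
        got = sorted([out["worst"].delta_qale_disc, out["best"].delta_qale_disc])
        assert got == pytest.approx(sorted([manual[-1], manual[1]]))


class TestOneWaySA:
    def test_zero_se_parameter_has_zero_range(self, ref_profile, params1, cfg, iv):
        import dataclasses

        vcov = np.asarray(params1.vcov).copy()
        names = list(params1.parameter_ordering())
        i = names.index("decrement.stroke")
        vcov[i, :] = 0.0
        vcov[:, i] = 0.0
        frozen = dataclasses.replace(params1, vcov=vcov)
        table = one_way_sa(
            ref_profile, iv, frozen, cfg, parameters=["decrement.stroke"]
        )
        assert table["range"].iloc[0] == 0.0

    def test_rows_sorted_by_descending_range(self, ref_profile, params1, cfg, iv):
        table = one_way_sa(
            ref_profile,
            iv,
            params1,
            cfg,
            parameters=[
                "event.nonfatal_chd.intercept",
                "event.fatal_cvd.intercept",
                "decrement.chd",
            ],
        )
        ranges = table["range"].dropna().to_numpy()
        assert np.all(np.diff(ranges) <= 0)

    def test_ranges_match_manual_evaluations(self, ref_profile, params1, cfg, iv):
        name = "event.fatal_cvd.intercept"
        table = one_way_sa(ref_profile, iv, params1, cfg, parameters=[name])
        names = list(params1.parameter_ordering())
        i = names.index(name)
        z = 1.959963984540054
        icers = []
        for sign in (-1, 1):
            vec = params1.parameter_vector()
            vec[i] += sign * z * params1.standard_errors()[i]
            icers.append(
                evaluate_intervention(
                    ref_profile, iv, params1.with_parameter_vector(vec), cfg
                ).icer
            )
        assert table["icer_low"].iloc[0] == pytest.approx(icers[0])
        assert table["icer_high"].iloc[0] == pytest.approx(icers[1])

    def test_unknown_parameter_rejected(self, ref_profile, params1, cfg, iv):
        with pytest.raises(ValidationError, match="not in vcov"):
            one_way_sa(ref_profile, iv, params1, cfg, parameters=["event.zzz"])
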