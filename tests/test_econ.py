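import numpy as np
import pytest

from cvdpolicy import (
    AnalysisError,
    Intervention,
    RiskFactorChange,
    RunConfig,
    ValidationError,
    apply_intervention,
    evaluate_intervention,
    event_rate_to_risk_factor,
    first_event_distribution,
    threshold_analysis,
)
from cvdpolicy.profiles import ProfilePath


@pytest.fixture
def cfg():
    return RunConfig(horizon=40)


@pytest.fixture
def beneficial():
    return Intervention(
        changes={
            "sbp": RiskFactorChange("add", -20),
            "cigarettes_per_day": RiskFactorChange("set", 0),
        },
        one_off_cost=500.0,
        annual_cost=40.0,
    )


class TestApplyIntervention:
    def test_zero_change_returns_identical_profile(self, ref_profile):
        assert apply_intervention(ref_profile, Intervention()) == ref_profile

    def test_perfect_profile_switch(self, ref_profile):
        """Non-smoker, SBP 100 and a cholesterol ratio of 3."""
        iv = Intervention(
            changes={
                "cigarettes_per_day": RiskFactorChange("set", 0),
                "sbp": RiskFactorChange("set", 100),
                "chol_ratio": RiskFactorChange("set", 3),
            }
        )
        out = apply_intervention(ref_profile, iv)
        assert out.cigarettes_per_day == 0
        assert out.sbp == 100.0
        assert out.chol_ratio == pytest.approx(3.0)
        assert out.hdl_chol == ref_profile.hdl_chol  # ratio acts on total chol

    def test_adherence_halves_the_expected_change(self, ref_profile):
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -20)}, adherence=0.5)
        out = apply_intervention(ref_profile, iv)
        assert out.sbp == pytest.approx(ref_profile.sbp - 10)

    def test_lag_and_decay_produce_a_trajectory(self, ref_profile):
        iv = Intervention(
            changes={"sbp": RiskFactorChange("add", -20)},
            onset_lag=2,
            annual_decay=0.5,
        )
        path = apply_intervention(ref_profile, iv, horizon=6)
        assert isinstance(path, ProfilePath)
        sbps = [path.at(k).sbp for k in range(6)]
        assert sbps[0] == sbps[1] == ref_profile.sbp
        assert sbps[2] == pytest.approx(ref_profile.sbp - 20)
        assert sbps[3] == pytest.approx(ref_profile.sbp - 10)
        assert sbps[4] == pytest.approx(ref_profile.sbp - 5)

    def test_out_of_range_change_clamped_with_warning(self, ref_profile):
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -500)})
        with pytest.warns(UserWarning, match="clamped"):
            out = apply_intervention(ref_profile, iv)
        assert out.base.sbp == 50.0
        assert out.warnings


class TestEvaluateIntervention:
    def test_null_intervention_is_exact_noop(self, ref_profile, params1, cfg):
        res = evaluate_intervention(ref_profile, Intervention(), params1, cfg)
        assert res.delta_le == 0.0
        assert res.delta_qale == 0.0
        assert res.delta_cost == 0.0
        assert res.delta_qale_disc == 0.0
        assert res.delta_cost_disc == 0.0
        assert res.icer is None
        assert res.flag == "undefined"

    def test_icer_equals_hand_computed_ratio(self, ref_profile, params1, cfg, beneficial):
        res = evaluate_intervention(ref_profile, beneficial, params1, cfg)
        assert res.flag == "icer"
        assert res.icer == pytest.approx(res.delta_cost_disc / res.delta_qale_disc)
        assert res.delta_qale_disc > 0

    def test_cost_free_beneficial_intervention_with_savings_is_dominant(
        self, ref_profile, params1, cfg
    ):
        """A free intervention that raises QALE and lowers downstream cost
        dominates."""
        import dataclasses

        # make the post-event phase expensive so avoiding events saves money
        cm = params1.cost_model
        pricey = dataclasses.replace(
            params1,
            cost_model=cm.replace(
                post_event={
                    ev: c.replace(intercept=c.intercept + 50000.0)
                    for ev, c in cm.post_event.items()
                }
            ),
        )
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -30)})
        res = evaluate_intervention(ref_profile, iv, pricey, cfg)
        assert res.delta_qale_disc > 0
        assert res.delta_cost_disc < 0
        assert res.flag == "dominant"
        assert res.icer is None

    def test_mixture_adherence_mixes_outcomes(self, ref_profile, params1, cfg):
        iv_full = Intervention(changes={"sbp": RiskFactorChange("add", -20)})
        iv_half = Intervention(
            changes={"sbp": RiskFactorChange("add", -20)}, adherence=0.5
        )
        full = evaluate_intervention(ref_profile, iv_full, params1, cfg)
        mixed = evaluate_intervention(
            ref_profile, iv_half, params1, cfg, adherence_mode="mixture"
        )
        assert mixed.delta_qale_disc == pytest.approx(0.5 * full.delta_qale_disc)


class TestThresholdAnalysis:
    def test_breakeven_cost_matches_closed_form(self, ref_profile, params1, cfg):
        """Varying a one-off cost, breakeven = lambda*dQALE - d(downstream
        cost) rescaled by the first-cycle discount factor."""
        lam = 20000.0
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -20)})
        res = evaluate_intervention(ref_profile, iv, params1, cfg)
        df0 = (1 + cfg.cost_rate) ** -0.5
        closed_form = (lam * res.delta_qale_disc - res.delta_cost_disc) / df0
        bisected = threshold_analysis(
            ref_profile, iv, params1, cfg, vary="cost", willingness_to_pay=lam
        )
        assert bisected == pytest.approx(closed_form, rel=1e-6)

    def test_breakeven_reproduces_icer_at_wtp(self, ref_profile, params1, cfg):
        lam = 25000.0
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -20)})
        cost = threshold_analysis(
            ref_profile, iv, params1, cfg, vary="cost", willingness_to_pay=lam
        )
        iv_at = Intervention(changes=iv.changes, one_off_cost=cost)
        res = evaluate_intervention(ref_profile, iv_at, params1, cfg)
        assert res.icer == pytest.approx(lam, rel=1e-6)

    def test_breakeven_cost_is_nonnegative_when_cost_saving(self, ref_profile, params1, cfg):
        iv = Intervention(changes={"sbp": RiskFactorChange("add", -20)})
        value = threshold_analysis(
            ref_profile, iv, params1, cfg, vary="cost", willingness_to_pay=30000.0
        )
        assert value >= 0

    def test_no_sign_change_raises(self, ref_profile, params1, cfg):
        null = Intervention()  # zero effect: NMB never positive
        with pytest.raises(AnalysisError):
            threshold_analysis(
                ref_profile, null, params1, cfg, vary="cost", willingness_to_pay=20000.0
            )

    def test_effect_scale_bracket_check(self, ref_profile, params1, cfg):
        free = Intervention(changes={"sbp": RiskFactorChange("add", -20)})
        with pytest.raises(AnalysisError, match="sign change"):
            # beneficial and free at every scale: no crossing in [0, 1]
            threshold_analysis(
                ref_profile, free, params1, cfg, vary="effect", willingness_to_pay=20000.0
            )


class TestEventRateToRiskFactor:
    def test_zero_target_change_needs_zero_adjustment(self, ref_profile, params1, cfg):
        assert event_rate_to_risk_factor(
            ref_profile, params1, "nonfatal_chd", 0.0, "sbp", cfg
        ) == 0.0

    def test_round_trip_reproduces_target_incidence(self, ref_profile, params1, cfg):
        target_change = -0.10
        delta = event_rate_to_risk_factor(
            ref_profile, params1, "nonfatal_chd", target_change, "sbp", cfg
        )
        assert delta < 0
        base = first_event_distribution(ref_profile, params1, cfg.horizon)
        moved = first_event_distribution(
            ref_profile.replace(sbp=ref_profile.sbp + delta), params1, cfg.horizon
        )
        achieved = moved.total_incidence("nonfatal_chd")
        wanted = (1 + target_change) * base.total_incidence("nonfatal_chd")
        assert achieved == pytest.approx(wanted, rel=1e-6)

    def test_unreachable_target_raises(self, ref_profile, params1, cfg):
        with pytest.raises(AnalysisError, match="unreachable"):
            event_rate_to_risk_factor(
                ref_profile, params1, "nonfatal_chd", -0.999, "sbp", cfg
            )


def test_intervention_validation():
    with pytest.raises(ValidationError):
        Intervention(changes={"age": -5})
    with pytest.raises(ValidationError):
        Intervention(adherence=1.5)
    with pytest.raises(ValidationError):
        RiskFactorChange("multiply", 2.0)
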