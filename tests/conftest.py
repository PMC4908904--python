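import numpy as np
import pytest

from cvdpolicy import (
    CostCurve,
    CostModel,
    DecrementSet,
    EventEquation,
    ParameterSet,
    RiskProfile,
    RunConfig,
    UtilityTable,
    make_synthetic_params,
)
from cvdpolicy.parameters import (
    FIRST_EVENTS,
    NONFATAL_EVENTS,
    POST_DEATH_EQS,
    POST_STATES,
    SUBSEQUENT_EVENTS,
)


def toy_params(
    sex: str = "male",
    intercepts: dict | None = None,
    post_death_intercept: float = -40.0,
    subsequent_intercept: float = -40.0,
    utility: float = 1.0,
    decrements: dict | None = None,
    pre_cost: float = 0.0,
    post_cost: float = 0.0,
    terminal_cost: float = 0.0,
) -> ParameterSet:
    """Minimal hand-set parameter set for degenerate-case tests.

    Intercept -40 gives probability 0 (to double precision); +40 gives 1.
    """
    intercepts = intercepts or {}
    events = {
        ev: EventEquation(intercept=intercepts.get(ev, -40.0))
        for ev in FIRST_EVENTS
    }
    for state in POST_STATES:
        name = POST_DEATH_EQS[state]
        events[name] = EventEquation(intercept=intercepts.get(name, post_death_intercept))
    subseq = {
        state: {
            ev: EventEquation(intercept=subsequent_intercept)
            for ev in SUBSEQUENT_EVENTS
        }
        for state in POST_STATES
    }
    decs = dict.fromkeys(SUBSEQUENT_EVENTS, 0.0)
    decs.update(decrements or {})
    cost_model = CostModel(
        pre_event=CostCurve(intercept=pre_cost),
        post_event={ev: CostCurve(intercept=post_cost) for ev in NONFATAL_EVENTS},
        terminal_cost=terminal_cost,
    )
    return ParameterSet(
        sex=sex,
        event_models=events,
        subsequent_event_models=subseq,
        utility_table=UtilityTable(np.full((2, 7, 5), utility)),
        decrements=DecrementSet(decs),
        cost_model=cost_model,
    )


@pytest.fixture(scope="session")
def params1():
    params, _ = make_synthetic_params(1)
    return params


@pytest.fixture(scope="session")
def truth1():
    _, truth = make_synthetic_params(1)
    return truth


@pytest.fixture
def ref_profile():
    return RiskProfile(
        age=60,
        sex="male",
        simd=60.8,
        family_history=False,
        diabetes=False,
        sbp=160.0,
        total_chol=7.0,
        hdl_chol=1.0,
        cigarettes_per_day=20,
    )


@pytest.fixture
def short_config():
    return RunConfig(horizon=10)
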