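"""Reward assembly, cost decomposition and comparison statistics."""

import numpy as np
import pytest

from asthma_cea.economics import (
    ae_cost_per_cycle,
    ae_disutility_per_cycle,
    build_cycle_rewards,
    classify,
    compare,
    drug_cost_per_cycle,
    indirect_cost_per_cse,
    net_monetary_benefit,
)
from asthma_cea.conversions import ValidationError
from asthma_cea.parameters import AEEvent, AEProfile, ArmProfile, EconomicInputs
from asthma_cea.states import CSE_STATES, HealthState
from asthma_cea.analyses import run_base_case


def _econ(**kw):
    defaults = dict(
        drug_unit_price=682.02,
        monitoring_cost_per_cycle=0.0,
        cse_cost_by_substate={"CSE_OCS": 0.0, "CSE_HOSP_ED": 0.0, "CSE_HOSP": 0.0},
        daily_wage=0.0,
        employment_rate_by_age=[((18.0, 130.0), 1.0)],
        presenteeism_days=0.0,
    )
    defaults.update(kw)
    return EconomicInputs(**defaults)


def test_drug_cost_amortized_over_dosing_interval():
    arm = ArmProfile("mepolizumab", 0.45, AEProfile(), drug_dose_mg=100,
                     dosing_interval_cycles=2)
    assert drug_cost_per_cycle(arm, _econ()) == pytest.approx(341.01)
    arm.dosing_interval_cycles = 1
    assert drug_cost_per_cycle(arm, _econ()) == pytest.approx(682.02)
    placebo = ArmProfile("placebo", 1.31, AEProfile(), drug_dose_mg=0)
    assert drug_cost_per_cycle(placebo, _econ()) == 0.0


def test_ae_cost_and_disutility_definitions():
    empty = ArmProfile("a", 0.0, AEProfile())
    assert ae_cost_per_cycle(empty) == 0.0
    assert ae_disutility_per_cycle(empty) == 0.0
    one = ArmProfile("a", 0.0, AEProfile([
        AEEvent("x", trial_incidence=0.26, cost_per_event=100.0, disutility=0.13)]))
    assert ae_cost_per_cycle(one, 26) == pytest.approx(0.26 / 26 * 100.0)
    assert ae_disutility_per_cycle(one, 26) == pytest.approx(0.26 * 0.13 / 26)


def test_fixture_ae_burden_lower_on_intervention(params):
    assert ae_disutility_per_cycle(params.intervention) < \
        ae_disutility_per_cycle(params.comparator)
    assert ae_cost_per_cycle(params.intervention) < \
        ae_cost_per_cycle(params.comparator)


def test_indirect_cost_human_capital_cases():
    econ = _econ(daily_wage=50.0)
    assert indirect_cost_per_cse(HealthState.CSE_OCS, 40.0, econ) == \
        pytest.approx(1 * 50.0)
    assert indirect_cost_per_cse(HealthState.CSE_HOSP, 40.0, econ) == \
        pytest.approx(6.4 * 50.0)
    # past the last employment band the employment rate is 0
    econ_retired = _econ(daily_wage=50.0,
                         employment_rate_by_age=[((18.0, 60.0), 1.0)])
    assert indirect_cost_per_cse(HealthState.CSE_HOSP, 70.0, econ_retired) == 0.0
    with pytest.raises(ValidationError):
        indirect_cost_per_cse(HealthState.NO_CSE, 40.0, econ)


def test_cycle_rewards_decomposition(params):
    rewards = build_cycle_rewards(params.comparator, 52.2, params)
    total = sum(rewards.cost_components.values())
    assert np.allclose(total, rewards.cost, atol=1e-9)
    # placebo: no drug component
    assert rewards.cost_components["drug"].sum() == 0.0
    no_cse = rewards.cost[HealthState.NO_CSE]
    assert no_cse == pytest.approx(
        params.econ.monitoring_cost_per_cycle
        + ae_cost_per_cycle(params.comparator, 26))
    # hospital-tier exacerbation cycles cost more than OCS ones
    assert rewards.cost[HealthState.CSE_HOSP] > rewards.cost[HealthState.CSE_OCS]
    assert rewards.cost[HealthState.DEATH] == 0.0
    assert rewards.utility[HealthState.DEATH] == 0.0


def test_zero_disutility_gives_uniform_state_utilities(params):
    p = params.copy()
    for k in p.util.disutility_by_substate:
        p.util.disutility_by_substate[k] = 0.0
    for arm in p.arms:
        arm.ae_profile.events = []
    rewards = build_cycle_rewards(p.arms[0], 52.2, p)
    expected = p.util.u_no_cse / 26
    for s in (HealthState.NO_CSE, *CSE_STATES):
        assert rewards.utility[s] == pytest.approx(expected, abs=1e-12)


def test_utility_floor_at_zero(params):
    p = params.copy()
    p.util.disutility_by_substate["CSE_HOSP"] = 0.99
    rewards = build_cycle_rewards(p.arms[1], 52.2, p)
    assert rewards.utility[HealthState.CSE_HOSP] == 0.0


@pytest.mark.parametrize(
    "dc, de, classification, has_icer",
    [
        (399.17, 0.47028, "icer", True),
        (-10.0, 0.1, "dominant", True),
        (10.0, -0.1, "dominated", True),
        (-10.0, -0.1, "icer", True),   # SW quadrant: a ratio, no dominance
        (0.0, 0.1, "icer", True),      # free gain: ICER 0
        (0.0, -0.1, "icer", True),
        (10.0, 0.0, "dominated", False),
        (-10.0, 0.0, "dominant", False),
        (0.0, 0.0, "tie", False),
    ],
)
def test_classification_sign_grid(dc, de, classification, has_icer):
    r = classify(dc, de)
    assert r.classification == classification
    assert (r.icer is not None) == has_icer
    assert r.icer_undefined == (de == 0.0)


def test_icer_identity_from_printed_increments():
    """The printed increments reproduce the printed ICER to the cent."""
    r = classify(399.17, 0.47028)
    assert r.icer == pytest.approx(848.79, abs=0.01)


def test_compare_identical_traces_flagged(base_case):
    trace = base_case.trace_comparator
    r = compare(trace, trace)
    assert r.delta_cost == 0.0 and r.delta_qaly == 0.0
    assert r.icer_undefined and r.classification == "tie"


def test_net_monetary_benefit():
    r = classify(399.17, 0.47028)
    assert net_monetary_benefit(r, 15_217.0) > 0
    assert net_monetary_benefit(r, r.icer) == pytest.approx(0.0, abs=1e-6)
    assert net_monetary_benefit(r, 0.0) < 0
    with pytest.raises(ValidationError):
        net_monetary_benefit(r, -1.0)


def test_drug_price_monotonicity(params, base_case):
    """Raising the drug price raises intervention-arm cost and the ICER."""
    p = params.copy()
    p.econ.drug_unit_price *= 1.5
    dearer = run_base_case(p, check_invariants=False)
    assert dearer.trace_intervention.cumulative_cost > \
        base_case.trace_intervention.cumulative_cost
    assert dearer.result.icer > base_case.result.icer


def test_higher_placebo_burden_weakly_lowers_icer(params, base_case):
    """More avoidable exacerbation burden (RR fixed) favours the biologic."""
    p = params.copy()
    rr = p.point_estimate("derived.cse_rr")
    p.comparator.annual_cse_rate *= 1.3
    p.apply("derived.cse_rr", rr)
    heavier = run_base_case(p, check_invariants=False)
    assert heavier.result.icer <= base_case.result.icer + 1e-9
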