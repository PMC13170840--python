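"""Transition matrices, cohort traces and the microsimulation oracle."""

import numpy as np
import pytest

from asthma_cea.conversions import ValidationError
from asthma_cea.markov import (
    build_transition_matrix,
    microsim_oracle,
    run_cohort,
)
from asthma_cea.parameters import annual_event_rate_to_cycle, annual_prob_to_cycle
from asthma_cea.states import CSE_STATES, HealthState
from asthma_cea.synthetic import random_parameters


def test_transition_matrix_structure(params):
    m = build_transition_matrix(params.comparator, 52.0, params).probs
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    p_death = m[HealthState.NO_CSE, HealthState.DEATH]
    cse_mass = m[HealthState.NO_CSE, list(CSE_STATES)].sum()
    assert cse_mass == pytest.approx((1 - p_death) * 0.05038, abs=5e-6)
    # tunnel: CSE states go only to NO_CSE or DEATH
    for s in CSE_STATES:
        assert m[s, HealthState.NO_CSE] + m[s, HealthState.DEATH] == \
            pytest.approx(1.0, abs=1e-12)
    assert m[HealthState.DEATH, HealthState.DEATH] == 1.0


def test_transition_matrix_zero_rate_and_immortal(params):
    p = params.copy()
    p.intervention.annual_cse_rate = 0.0
    m = build_transition_matrix(p.intervention, 52.0, p).probs
    row = m[HealthState.NO_CSE]
    assert row[list(CSE_STATES)].sum() == 0.0
    assert row[HealthState.NO_CSE] + row[HealthState.DEATH] == \
        pytest.approx(1.0, abs=1e-12)

    p.mortality.no_cse_cycle = [0.0] * len(p.mortality.bands)
    p.mortality.cse_cycle = [0.0] * len(p.mortality.bands)
    m = build_transition_matrix(p.comparator, 52.0, p).probs
    assert m[:, HealthState.DEATH].sum() == pytest.approx(1.0)  # death row only


def test_age_outside_mortality_coverage_names_age(params):
    with pytest.raises(ValidationError, match="20"):
        build_transition_matrix(params.comparator, 20.0, params)


def test_fixture_trace_invariants(base_case):
    for trace in (base_case.trace_intervention, base_case.trace_comparator):
        trace.validate()
        occ = trace.occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(occ[:, HealthState.DEATH]) >= -1e-12).all()
        assert trace.cumulative_qaly > 0
        assert trace.cumulative_cost > 0


def _pristine_one_year(params, utility):
    """No mortality, no exacerbations, no discounting, 1-year horizon."""
    p = params.copy()
    p.settings.annual_discount_rate = 0.0
    p.settings.max_age = p.settings.start_age + 1.0
    for arm in p.arms:
        arm.annual_cse_rate = 0.0
        arm.ae_profile.events = []
    zeros = [0.0] * len(p.mortality.bands)
    p.mortality.no_cse_annual = zeros
    p.mortality.cse_annual = zeros
    p.mortality.no_cse_cycle = zeros
    p.mortality.cse_cycle = zeros
    p.util.u_no_cse = utility
    return p


def test_closed_form_qaly_one_year(params):
    """u * t: one undiscounted deathless year at utility 0.84 gives 0.84 QALY."""
    p = _pristine_one_year(params, 0.84)
    trace = run_cohort(p.intervention, p)
    assert trace.n_cycles == 26
    assert trace.cumulative_qaly == pytest.approx(0.84, abs=1e-12)


def test_half_cycle_correction_noop_with_constant_occupancy(params):
    """With no deaths and constant rewards the trapezoid changes nothing."""
    p = _pristine_one_year(params, 0.7)
    p.settings.half_cycle_correction = True
    on = run_cohort(p.intervention, p)
    p.settings.half_cycle_correction = False
    off = run_cohort(p.intervention, p)
    assert on.cumulative_qaly == pytest.approx(off.cumulative_qaly, abs=1e-9)
    assert on.cumulative_cost == pytest.approx(off.cumulative_cost, abs=1e-9)


def test_half_cycle_correction_moves_toward_midpoint(params):
    """With mortality, the corrected total lies between the uncorrected
    entry-occupancy total and the exit-occupancy total."""
    p = params.copy()
    p.settings.half_cycle_correction = False
    entry = run_cohort(p.comparator, p)
    p.settings.half_cycle_correction = True
    corrected = run_cohort(p.comparator, p)
    assert corrected.cumulative_qaly < entry.cumulative_qaly


def test_cycle_length_refinement_stability(params):
    """Re-parameterising at a 1-week cycle changes lifetime QALYs < 1%.

    Per-cycle quantities are re-expressed for the finer grid: mortality via
    the probability conversion, dosing interval and flat monitoring cost per
    cycle rescaled, and the per-episode disutility decrement doubled because
    the exacerbation tunnel now lasts half as long.
    """
    coarse = run_cohort(params.comparator, params)

    fine = params.copy()
    fine.settings.cycles_per_year = 52
    fine.settings.cycle_length_weeks = 1.0
    for arm in fine.arms:
        arm.dosing_interval_cycles *= 2
    fine.econ.monitoring_cost_per_cycle /= 2
    for k in fine.util.disutility_by_substate:
        fine.util.disutility_by_substate[k] = min(
            2 * fine.util.disutility_by_substate[k], fine.util.u_no_cse)
    from asthma_cea.mortality import MortalityTable
    fine.mortality = MortalityTable(
        bands=fine.mortality.bands,
        no_cse_annual=fine.mortality.no_cse_annual,
        cse_annual=fine.mortality.cse_annual,
        cycles_per_year=52,
    )
    trace = run_cohort(fine.comparator, fine)
    rel = abs(trace.cumulative_qaly - coarse.cumulative_qaly) / coarse.cumulative_qaly
    assert rel < 0.01


def test_trace_conservation_on_random_parameter_sets():
    """Occupancy conservation and death monotonicity over 100 random sets."""
    for seed in range(100):
        p = random_parameters(seed)
        trace = run_cohort(p.arms[seed % 2], p, check_invariants=True)
        occ = trace.occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(occ[:, HealthState.DEATH]) >= -1e-9).all()


def test_microsim_reproducible_and_deterministic_limit(params):
    a = microsim_oracle(params.intervention, params, n_individuals=200, seed=7)
    b = microsim_oracle(params.intervention, params, n_individuals=200, seed=7)
    assert a.mean_cost == b.mean_cost and a.mean_qaly == b.mean_qaly

    # with all probabilities 0 or 1 the microsimulation is exact
    p = _pristine_one_year(params, 0.5)
    cohort = run_cohort(p.intervention, p)
    micro = microsim_oracle(p.intervention, p, n_individuals=10, seed=1)
    assert micro.mean_qaly == pytest.approx(cohort.cumulative_qaly, abs=1e-12)
    assert micro.mean_cost == pytest.approx(cohort.cumulative_cost, abs=1e-9)


def test_microsim_agrees_with_cohort_on_fixture(params):
    """Cohort totals within 3 Monte-Carlo SEs of the individual-level means."""
    cohort = run_cohort(params.comparator, params)
    micro = microsim_oracle(params.comparator, params,
                            n_individuals=20_000, seed=42)
    assert abs(micro.mean_qaly - cohort.cumulative_qaly) < 3 * micro.se_qaly
    assert abs(micro.mean_cost - cohort.cumulative_cost) < 3 * micro.se_cost
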