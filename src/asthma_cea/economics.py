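"""Per-cycle cost and utility rewards, and arm-comparison statistics.

Cost components per 2-week cycle and health state:

* drug acquisition — unit price amortised over the dosing interval;
* routine monitoring — flat per-cycle cost while alive;
* adverse-event management — trial-window AE incidences spread uniformly
  over the cycles of a year and multiplied by per-event costs; attached to
  every living state (the burden follows the treatment arm, not the
  exacerbation state);
* exacerbation management — substate-tier cost on exacerbation cycles only;
* productivity loss (human-capital) — missed workdays plus presenteeism days
  times the daily wage, scaled by the age-band employment rate, accrued on
  exacerbation cycles only.

Utilities: baseline utility minus the frequency-weighted AE disutility, and
additionally the substate disutility during an exacerbation cycle; the
per-cycle utility is floored at 0 (extreme sensitivity draws could otherwise
push it negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .conversions import ValidationError
from .parameters import ArmProfile, EconomicInputs, ModelParameters
from .states import ALIVE_STATES, CSE_STATES, N_STATES, HealthState

if TYPE_CHECKING:  # pragma: no cover
    from .markov import MarkovTrace

COST_COMPONENTS = ("drug", "monitoring", "ae", "cse_management", "indirect")

_MISSED_DAYS_FIELD = {
    HealthState.CSE_OCS: "missed_days_outpatient",
    HealthState.CSE_HOSP_ED: "missed_days_hospitalized",
    HealthState.CSE_HOSP: "missed_days_hospitalized",
}


def drug_cost_per_cycle(arm: ArmProfile, econ: EconomicInputs) -> float:
    """Amortised drug acquisition cost per cycle.

    The unit price is quoted per 100 mg dose; a dose every
    ``dosing_interval_cycles`` cycles spreads ``price * dose/100`` evenly
    over the interval.
    """
    doses_per_cycle = 1.0 / arm.dosing_interval_cycles
    return econ.drug_unit_price * (arm.drug_dose_mg / 100.0) * doses_per_cycle


def ae_cost_per_cycle(arm: ArmProfile, cycles_per_year: int = 26) -> float:
    """Adverse-event management cost per cycle for one arm.

    Trial-window incidences are treated as annual frequencies and divided by
    the number of cycles per year, then weighted by per-event costs.
    """
    return sum(
        e.trial_incidence / cycles_per_year * e.cost_per_event
        for e in arm.ae_profile.events
    )


def ae_disutility_per_cycle(arm: ArmProfile, cycles_per_year: int = 26) -> float:
    """Frequency-weighted adverse-event utility decrement per cycle."""
    return sum(
        e.trial_incidence / cycles_per_year * e.disutility
        for e in arm.ae_profile.events
    )


def indirect_cost_per_cse(state: HealthState, age: float,
                          econ: EconomicInputs) -> float:
    """Human-capital productivity loss for one exacerbation cycle.

    Missed paid workdays (1 outpatient, 6.4 for the hospital tiers by
    default) plus presenteeism days, valued at the daily wage and scaled by
    the employment rate of the age band (0 beyond the last band).
    """
    if state not in CSE_STATES:
        raise ValidationError(f"indirect cost is defined only for CSE states, "
                              f"got {state.name}")
    days = getattr(econ, _MISSED_DAYS_FIELD[state]) + econ.presenteeism_days
    return days * econ.daily_wage * econ.employment_rate(age)


@dataclass
class CycleRewards:
    """Undiscounted one-cycle rewards per health state for one arm at one age.

    ``cost`` and ``utility`` are indexed by :class:`HealthState`; ``utility``
    is already scaled to QALYs per cycle (utility x cycle length in years).
    ``cost_components`` decomposes ``cost`` into the standard ledgers.
    """

    cost: np.ndarray
    utility: np.ndarray
    cost_components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dead = HealthState.DEATH
        if self.cost[dead] != 0 or self.utility[dead] != 0:
            raise ValidationError("death rewards must be zero")
        if (self.cost < 0).any() or (self.utility < 0).any():
            raise ValidationError("rewards must be non-negative")


def build_cycle_rewards(arm: ArmProfile, age: float,
                        params: ModelParameters) -> CycleRewards:
    """Assemble the per-state cost and utility rewards for one cycle.

    Drug cost accrues only while the cycle-start age is inside the dosing
    window; adverse-event cost and disutility only inside the AE accrual
    window (both lifetime unless bounded in the settings).
    """
    cpy = params.settings.cycles_per_year
    cycle_years = params.settings.cycle_years

    drug = drug_cost_per_cycle(arm, params.econ) \
        if params.settings.on_drug(age) else 0.0
    monitoring = params.econ.monitoring_cost_per_cycle
    in_ae = params.settings.in_ae_window(age)
    ae_cost = ae_cost_per_cycle(arm, cpy) if in_ae else 0.0
    ae_disu = ae_disutility_per_cycle(arm, cpy) if in_ae else 0.0

    comp = {name: np.zeros(N_STATES) for name in COST_COMPONENTS}
    utility = np.zeros(N_STATES)
    for s in ALIVE_STATES:
        comp["drug"][s] = drug
        comp["monitoring"][s] = monitoring
        comp["ae"][s] = ae_cost
    for s in CSE_STATES:
        comp["cse_management"][s] = params.econ.cse_cost_by_substate[s.name]
        comp["indirect"][s] = indirect_cost_per_cse(s, age, params.econ)

    u_base = params.util.u_no_cse - ae_disu
    utility[HealthState.NO_CSE] = max(u_base, 0.0) * cycle_years
    for s in CSE_STATES:
        u = u_base - params.util.disutility_by_substate[s.name]
        utility[s] = max(u, 0.0) * cycle_years

    cost = sum(comp.values())
    return CycleRewards(cost=cost, utility=utility, cost_components=comp)


# ---------------------------------------------------------------------------
# comparison statistics


@dataclass
class CEResult:
    """Incremental comparison of two arms (a = intervention, b = comparator)."""

    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str  # "icer" | "dominant" | "dominated" | "tie"
    icer_undefined: bool = False

    def summary(self) -> dict:
        return {
            "cost_intervention": self.cost_a,
            "cost_comparator": self.cost_b,
            "qaly_intervention": self.qaly_a,
            "qaly_comparator": self.qaly_b,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
        }


def classify(delta_cost: float, delta_qaly: float,
             qaly_tol: float = 0.0) -> CEResult:
    """Build a :class:`CEResult` from raw totals encoded as deltas only.

    Exposed separately so the sign/dominance logic can be exercised on all
    nine (sign of delta-cost, sign of delta-QALY) combinations.
    """
    return _compare_totals(delta_cost, 0.0, delta_qaly, 0.0, qaly_tol)


def _compare_totals(cost_a: float, cost_b: float, qaly_a: float, qaly_b: float,
                    qaly_tol: float = 0.0) -> CEResult:
    dc = cost_a - cost_b
    de = qaly_a - qaly_b
    icer: float | None
    undefined = False
    if abs(de) <= qaly_tol or de == 0.0:
        icer = None
        undefined = True
        if dc > 0:
            classification = "dominated"
        elif dc < 0:
            classification = "dominant"
        else:
            classification = "tie"
    elif de > 0 and dc < 0:
        icer = dc / de  # negative: cost-saving and more effective
        classification = "dominant"
    elif de < 0 and dc > 0:
        icer = dc / de
        classification = "dominated"
    else:
        icer = dc / de
        classification = "icer"
    return CEResult(cost_a=cost_a, cost_b=cost_b, qaly_a=qaly_a, qaly_b=qaly_b,
                    delta_cost=dc, delta_qaly=de, icer=icer,
                    classification=classification, icer_undefined=undefined)


def compare(trace_a: "MarkovTrace", trace_b: "MarkovTrace") -> CEResult:
    """ICER / dominance comparison of two cohort traces.

    ``trace_a`` is the intervention, ``trace_b`` the comparator; both must
    come from the same settings (horizon, discounting).
    """
    return _compare_totals(trace_a.cumulative_cost, trace_b.cumulative_cost,
                           trace_a.cumulative_qaly, trace_b.cumulative_qaly)


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost`` at a threshold."""
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * result.delta_qaly - result.delta_cost
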