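"""Cohort Markov engine: transition matrices, discounted half-cycle-corrected
traces, and an individual-level microsimulation oracle.

The cohort starts fully in the stable (no-exacerbation) state at the mean
cohort age and is advanced in 2-week cycles until the terminal age (default
100 years) or until the living fraction is numerically exhausted.  Each
cycle the cohort faces, from the stable state, state-specific asthma death
and entry into one of three exacerbation tunnel states; exacerbation
survivors return to the stable state after one cycle.

Rewards are accrued with an optional half-cycle correction (trapezoidal
average of the occupancy at cycle entry and exit) and discounted at the
annual rate applied per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversions import ValidationError, annual_event_rate_to_cycle
from .economics import CycleRewards, build_cycle_rewards, COST_COMPONENTS
from .mortality import lookup_cycle_mortality
from .parameters import ArmProfile, ModelParameters
from .states import CSE_STATES, N_STATES, HealthState

_ROW_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Per-cycle transition probabilities at a given age (rows: from-state)."""

    probs: np.ndarray
    age_years: float

    def __post_init__(self) -> None:
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise ValidationError(f"transition matrix must be {N_STATES}x{N_STATES}")
        if (p < -_ROW_TOL).any() or (p > 1 + _ROW_TOL).any():
            raise ValidationError("transition probabilities must be in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValidationError("transition matrix rows must sum to 1")
        dead = HealthState.DEATH
        if not (p[dead, dead] == 1.0 and p[dead].sum() == 1.0):
            raise ValidationError("death must be absorbing")


def build_transition_matrix(arm: ArmProfile, age: float,
                            params: ModelParameters) -> TransitionMatrix:
    """Transition matrix for one arm at one age.

    From the stable state: death first (state-specific per-cycle asthma
    mortality at this age), then, conditional on surviving, an exacerbation
    with the arm's per-cycle probability, allocated across severity
    substates by the event split.  From each exacerbation substate: death at
    the exacerbation-state mortality, otherwise return to the stable state.
    """
    m = np.zeros((N_STATES, N_STATES))
    table = params.mortality
    split = params.substate_split.as_dict()
    p_cse = annual_event_rate_to_cycle(arm.annual_cse_rate,
                                       params.settings.cycles_per_year)

    p_death_no = lookup_cycle_mortality(table, HealthState.NO_CSE, age)
    row = HealthState.NO_CSE
    m[row, HealthState.DEATH] = p_death_no
    for s in CSE_STATES:
        m[row, s] = (1.0 - p_death_no) * p_cse * split[s.name]
    m[row, row] = 1.0 - m[row].sum()

    p_death_cse = lookup_cycle_mortality(table, HealthState.CSE_OCS, age)
    for s in CSE_STATES:
        m[s, HealthState.DEATH] = p_death_cse
        m[s, HealthState.NO_CSE] = 1.0 - p_death_cse

    m[HealthState.DEATH, HealthState.DEATH] = 1.0
    return TransitionMatrix(probs=m, age_years=age)


@dataclass
class MarkovTrace:
    """Per-cycle state occupancy and discounted reward accumulators for one arm.

    ``occupancy`` has ``n_cycles + 1`` rows (entry occupancy of every cycle
    plus the final exit occupancy); ``cost_per_cycle`` / ``qaly_per_cycle``
    hold discounted per-cycle accruals, so the cumulative totals are their
    plain sums.  ``cost_components`` holds the discounted component ledgers
    (drug, monitoring, AE, exacerbation management, indirect).
    """

    arm_name: str
    occupancy: np.ndarray
    ages: np.ndarray
    cost_per_cycle: np.ndarray
    qaly_per_cycle: np.ndarray
    cumulative_cost: float
    cumulative_qaly: float
    n_cycles: int
    cost_components: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValidationError("occupancy vectors must sum to 1")
        if (occ < -_ROW_TOL).any():
            raise ValidationError("occupancy must be non-negative")
        dead = occ[:, HealthState.DEATH]
        if (np.diff(dead) < -_ROW_TOL).any():
            raise ValidationError("death occupancy must be non-decreasing")
        if abs(self.cost_per_cycle.sum() - self.cumulative_cost) > 1e-9 * max(
                1.0, abs(self.cumulative_cost)):
            raise ValidationError("cumulative cost disagrees with per-cycle sum")
        if abs(self.qaly_per_cycle.sum() - self.cumulative_qaly) > 1e-9 * max(
                1.0, abs(self.cumulative_qaly)):
            raise ValidationError("cumulative QALY disagrees with per-cycle sum")

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        df = pd.DataFrame(self.occupancy[:n],
                          columns=[s.name for s in HealthState])
        df.insert(0, "cycle", np.arange(n))
        df.insert(1, "age", self.ages[:n])
        df["discounted_cost"] = self.cost_per_cycle
        df["discounted_qaly"] = self.qaly_per_cycle
        return df


def _age_caches(arm: ArmProfile, params: ModelParameters):
    """Per-integer-age caches of transition matrices and reward vectors.

    Rewards additionally key on whether the cycle lies inside the drug and
    adverse-event accrual windows, which can cut across an integer age.
    Assumes mortality and employment band edges fall on integer ages.
    """
    s = params.settings
    matrices: dict[int, np.ndarray] = {}
    rewards: dict[tuple[int, bool, bool], CycleRewards] = {}

    def get(age: float) -> tuple[np.ndarray, CycleRewards]:
        band = int(age)
        if band not in matrices:
            matrices[band] = build_transition_matrix(arm, float(band), params).probs
        key = (band, s.on_drug(age), s.in_ae_window(age))
        if key not in rewards:
            rewards[key] = build_cycle_rewards(arm, age, params)
        return matrices[band], rewards[key]

    return get


def run_cohort(arm: ArmProfile, params: ModelParameters,
               check_invariants: bool = True) -> MarkovTrace:
    """Run the discounted, half-cycle-corrected cohort simulation for one arm.

    Age advances continuously (``start_age + k / cycles_per_year``); the
    mortality and employment lookups use the containing integer age.  The
    run stops at ``max_age`` (remaining cohort censored, no further accrual)
    or when living occupancy falls below 1e-9.
    """
    s = params.settings
    cpy = s.cycles_per_year
    n_max = int(math.ceil((s.max_age - s.start_age) * cpy))
    get = _age_caches(arm, params)

    occ = np.zeros((n_max + 1, N_STATES))
    occ[0, HealthState.NO_CSE] = 1.0
    cost_vecs = np.zeros((n_max, N_STATES))
    util_vecs = np.zeros((n_max, N_STATES))
    comp_vecs = {name: np.zeros((n_max, N_STATES)) for name in COST_COMPONENTS}
    ages = s.start_age + np.arange(n_max + 1) / cpy

    n = 0
    for k in range(n_max):
        age = ages[k]
        if age >= s.max_age:
            break
        matrix, rewards = get(age)
        occ[k + 1] = occ[k] @ matrix
        cost_vecs[k] = rewards.cost
        util_vecs[k] = rewards.utility
        for name in COST_COMPONENTS:
            comp_vecs[name][k] = rewards.cost_components[name]
        n = k + 1
        if occ[k + 1, HealthState.DEATH] > 1.0 - 1e-9:
            break

    occ = occ[: n + 1]
    ages_out = ages[: n + 1]
    if s.half_cycle_correction:
        weights = 0.5 * (occ[:-1] + occ[1:])
    else:
        weights = occ[:-1]
    disc = (1.0 + s.annual_discount_rate) ** (-np.arange(n) / cpy)
    cost_per_cycle = disc * np.einsum("ij,ij->i", weights, cost_vecs[:n])
    qaly_per_cycle = disc * np.einsum("ij,ij->i", weights, util_vecs[:n])
    components = {
        name: float(np.sum(disc * np.einsum("ij,ij->i", weights, comp_vecs[name][:n])))
        for name in COST_COMPONENTS
    }

    trace = MarkovTrace(
        arm_name=arm.name,
        occupancy=occ,
        ages=ages_out,
        cost_per_cycle=cost_per_cycle,
        qaly_per_cycle=qaly_per_cycle,
        cumulative_cost=float(cost_per_cycle.sum()),
        cumulative_qaly=float(qaly_per_cycle.sum()),
        n_cycles=n,
        cost_components=components,
    )
    if check_invariants:
        trace.validate()
    return trace


@dataclass
class MicrosimResult:
    """Monte-Carlo estimates from the individual-level oracle."""

    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n_individuals: int


def microsim_oracle(arm: ArmProfile, params: ModelParameters,
                    n_individuals: int, seed: int) -> MicrosimResult:
    """Individual-level simulation with the same probabilities and rewards.

    Serves as an independent check of :func:`run_cohort`: the cohort trace
    is the exact expectation of these trajectories, so the sample means
    converge to the cohort totals as ``n_individuals`` grows.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    s = params.settings
    cpy = s.cycles_per_year
    n_max = int(math.ceil((s.max_age - s.start_age) * cpy))
    get = _age_caches(arm, params)
    rng = np.random.default_rng(seed)

    state = np.full(n_individuals, int(HealthState.NO_CSE), dtype=np.int64)
    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    hcc = s.half_cycle_correction

    for k in range(n_max):
        age = s.start_age + k / cpy
        if age >= s.max_age:
            break
        matrix, rewards = get(age)
        cum = matrix.cumsum(axis=1)
        u = rng.random(n_individuals)
        new_state = np.empty_like(state)
        for st in range(N_STATES):
            mask = state == st
            if mask.any():
                new_state[mask] = np.searchsorted(cum[st], u[mask], side="right")
        np.minimum(new_state, N_STATES - 1, out=new_state)
        disc = (1.0 + s.annual_discount_rate) ** (-k / cpy)
        if hcc:
            c = 0.5 * (rewards.cost[state] + rewards.cost[new_state])
            q = 0.5 * (rewards.utility[state] + rewards.utility[new_state])
        else:
            c = rewards.cost[state]
            q = rewards.utility[state]
        cost += disc * c
        qaly += disc * q
        state = new_state
        if (state == HealthState.DEATH).all():
            break

    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / math.sqrt(n_individuals))
        if n_individuals > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / math.sqrt(n_individuals))
        if n_individuals > 1 else 0.0,
        n_individuals=n_individuals,
    )
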