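"""Orchestration of the base-case, subgroup, deterministic and probabilistic
analyses.

Deterministic sensitivity analysis (DSA) perturbs one parameter path at a
time to the low and high end of its range (default +/-20% around the point
estimate, confidence intervals for rate ratios, a literature range for the
baseline utility) and records both incremental cost-effectiveness ratios;
entries are ordered by absolute ICER spread for a tornado display.

Probabilistic sensitivity analysis (PSA) draws every uncertain parameter
from its assigned distribution, using one independent random stream per
parameter derived from the master seed, so adding or removing a parameter
does not reshuffle the draws of the others.  The cost-effectiveness
acceptability curve (CEAC) is the fraction of draws with positive
incremental net monetary benefit over a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversions import ValidationError
from .economics import CEResult, compare
from .markov import MarkovTrace, run_cohort
from .parameters import DERIVED_PATHS, ModelParameters, SubgroupSpec

logger = logging.getLogger(__name__)


@dataclass
class BaseCaseResult:
    """Base-case comparison plus the underlying traces and cost ledgers."""

    result: CEResult
    trace_intervention: MarkovTrace
    trace_comparator: MarkovTrace

    def cost_composition(self) -> pd.DataFrame:
        """Discounted cost per arm and component (the S10-style breakdown)."""
        rows = []
        for trace in (self.trace_intervention, self.trace_comparator):
            for component, total in trace.cost_components.items():
                rows.append({"arm": trace.arm_name, "component": component,
                             "discounted_total": total})
            rows.append({"arm": trace.arm_name, "component": "total",
                         "discounted_total": trace.cumulative_cost})
        return pd.DataFrame(rows)


def run_base_case(params: ModelParameters,
                  check_invariants: bool = True) -> BaseCaseResult:
    """Run both arms through the cohort engine and compare them."""
    trace_a = run_cohort(params.intervention, params, check_invariants)
    trace_b = run_cohort(params.comparator, params, check_invariants)
    return BaseCaseResult(result=compare(trace_a, trace_b),
                          trace_intervention=trace_a, trace_comparator=trace_b)


def run_subgroups(params: ModelParameters) -> list[tuple[SubgroupSpec, CEResult]]:
    """Per-subgroup comparisons.

    The comparator (placebo) exacerbation rate is shared by all subgroups;
    the intervention rate is the placebo rate times the subgroup rate ratio.
    All other parameters are shared.
    """
    if not params.subgroups:
        raise ValidationError("subgroups: none defined")
    out = []
    for sg in params.subgroups:
        if sg.rr <= 0:
            raise ValidationError(f"subgroups.{sg.name}: rr must be > 0")
        p = params.copy()
        p.intervention.annual_cse_rate = p.comparator.annual_cse_rate * sg.rr
        out.append((sg, run_base_case(p, check_invariants=False).result))
    return out


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis


@dataclass
class TornadoEntry:
    """One-at-a-time perturbation record for a single parameter path."""

    parameter_path: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    classification_at_low: str
    classification_at_high: str
    spread: float


_DOMAIN_CAPS = {
    "util.u_no_cse": (0.0, 1.0),
    "substate_split.p_ocs": (0.0, 1.0),
    "substate_split.p_hosp_ed": (0.0, 1.0),
    "substate_split.p_hosp": (0.0, 1.0),
    "settings.annual_discount_rate": (0.0, 0.999),
}


def _clamped(path: str, value: float) -> float:
    low, high = _DOMAIN_CAPS.get(path, (0.0, np.inf))
    if path.endswith("trial_incidence") or path.endswith("disutility"):
        low, high = 0.0, 1.0
    if value < low or value > high:
        clamped = min(max(value, low), high)
        logger.warning("DSA %s: value %.6g outside valid domain; clamped to %.6g",
                       path, value, clamped)
        return clamped
    return value


def _ordering_icer(result: CEResult) -> float:
    """ICER-like scalar used for tornado ordering.

    Dominant outcomes carry a negative ratio (cost saving per QALY gained),
    preserving a total order; undefined ratios (no QALY difference) order by
    the sign of the cost difference at an arbitrarily large magnitude.
    """
    if result.icer is not None:
        return result.icer
    return np.inf if result.delta_cost > 0 else -np.inf


def run_dsa(params: ModelParameters) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis over ``params.dsa_ranges``.

    Each perturbation works on a copy; after the sweep the base case is
    re-run and checked against the pre-sweep base case, guaranteeing no
    perturbation leaked into the shared parameter set.
    """
    if not params.dsa_ranges:
        raise ValidationError("dsa_ranges: none defined")
    base = run_base_case(params, check_invariants=False).result
    entries = []
    for path, (low, high) in params.dsa_ranges.items():
        results = {}
        for end, raw in (("low", low), ("high", high)):
            value = _clamped(path, raw)
            p = params.copy()
            p.apply(path, value)
            results[end] = run_base_case(p, check_invariants=False).result
        r_low, r_high = results["low"], results["high"]
        entries.append(TornadoEntry(
            parameter_path=path,
            low_value=_clamped(path, low),
            high_value=_clamped(path, high),
            icer_at_low=_ordering_icer(r_low),
            icer_at_high=_ordering_icer(r_high),
            classification_at_low=r_low.classification,
            classification_at_high=r_high.classification,
            spread=abs(_ordering_icer(r_high) - _ordering_icer(r_low)),
        ))
    base_again = run_base_case(params, check_invariants=False).result
    if abs(base_again.delta_cost - base.delta_cost) > 1e-9 or \
            abs(base_again.delta_qaly - base.delta_qaly) > 1e-12:
        raise ValidationError("DSA failed to restore the base case")
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Monte-Carlo draws of (incremental cost, incremental QALY)."""

    draws: np.ndarray  # shape (n, 2): columns delta_cost, delta_qaly
    n_iterations: int
    seed: int

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.draws[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=["delta_cost", "delta_qaly"])


def _path_rng(master_seed: int, path: str) -> np.random.Generator:
    """Independent, order-insensitive stream for one parameter path."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(path.encode())]))


_PSA_DOMAINS = {
    "util.u_no_cse": (0.0, 1.0),
}


def _draw_valid(spec, rng, path: str, max_attempts: int = 100) -> float:
    low, high = _PSA_DOMAINS.get(path, (0.0, np.inf))
    if path.endswith("trial_incidence") or path.endswith("disutility") or \
            path.startswith("substate_split."):
        low, high = 0.0, 1.0
    for _ in range(max_attempts):
        v = spec.sample(rng)
        if low <= v <= high:
            return v
    raise ValidationError(
        f"psa_specs.{path}: no valid draw within {max_attempts} attempts")


def run_psa(params: ModelParameters, n: int, seed: int) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` Monte-Carlo iterations.

    Every uncertain parameter is drawn from its :class:`DistributionSpec`;
    derived paths (the exacerbation rate ratio) are applied after the
    ordinary draws so the intervention rate is consistent with the drawn
    placebo rate.  Fully deterministic given ``seed``.
    """
    if n < 1:
        raise ValidationError("PSA iterations must be >= 1")
    if not params.psa_specs:
        raise ValidationError("psa_specs: none defined")
    ordinary = [p for p in params.psa_specs if p not in DERIVED_PATHS]
    derived = [p for p in params.psa_specs if p in DERIVED_PATHS]
    rngs = {p: _path_rng(seed, p) for p in params.psa_specs}

    draws = np.empty((n, 2))
    for i in range(n):
        p = params.copy()
        for path in ordinary:
            p.apply(path, _draw_valid(params.psa_specs[path], rngs[path], path))
        for path in derived:
            p.apply(path, _draw_valid(params.psa_specs[path], rngs[path], path))
        r = run_base_case(p, check_invariants=False).result
        draws[i, 0] = r.delta_cost
        draws[i, 1] = r.delta_qaly
    return PSAResult(draws=draws, n_iterations=n, seed=seed)


@dataclass
class CEACPoint:
    wtp: float
    prob_cost_effective: float


def ceac(psa: PSAResult, wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each threshold: the fraction of draws with positive incremental net
    monetary benefit ``wtp * dQALY - dCost``.
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValidationError("CEAC grid must be non-empty")
    out = []
    for wtp in wtp_grid:
        nmb = wtp * psa.delta_qaly - psa.delta_cost
        out.append(CEACPoint(wtp=float(wtp),
                             prob_cost_effective=float(np.mean(nmb > 0))))
    return out


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


def default_wtp_grid(low: float = 0.0, high: float = 45_000.0,
                     step: float = 500.0) -> np.ndarray:
    """Default grid: covers the WTP band and the region around it."""
    return np.arange(low, high + step / 2, step)
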