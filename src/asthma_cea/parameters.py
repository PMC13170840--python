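"""Parameter data model, configuration IO and validation.

All model inputs live in a single :class:`ModelParameters` container: the two
treatment arms (annual exacerbation rates, adverse-event profiles, dosing),
the severity split of exacerbation events, economic and utility inputs, the
age-indexed mortality table, subgroup rate ratios, and the ranges /
distributions driving the sensitivity analyses.

Money is held internally in USD; any money field in a config may be written
as ``{cny: <amount>}`` and is divided by the configured exchange rate on
load.  Uncertain parameters are addressed by dotted *parameter paths* (e.g.
``econ.drug_unit_price`` or ``arms.placebo.ae_profile.pneumonia.cost_per_event``)
which must resolve to an existing scalar; the special path ``derived.cse_rr``
addresses the mepolizumab/placebo exacerbation rate ratio, re-deriving the
mepolizumab rate from the placebo rate whenever it is set.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .conversions import (
    ValidationError,
    annual_event_rate_to_cycle,
    annual_prob_to_cycle,
    cycle_prob_to_annual,
    per_cycle_discount_factor,
)
from .mortality import AgeBand, MortalityTable
from .states import CSE_STATES

__all__ = [
    "ValidationError",
    "annual_event_rate_to_cycle",
    "annual_prob_to_cycle",
    "cycle_prob_to_annual",
    "per_cycle_discount_factor",
    "AEEvent",
    "AEProfile",
    "ArmProfile",
    "CSESubstateSplit",
    "EconomicInputs",
    "UtilityInputs",
    "DistributionSpec",
    "ModelSettings",
    "SubgroupSpec",
    "ModelParameters",
    "load_parameters",
    "to_config",
    "resolve_path",
    "set_path",
    "scalar_paths",
    "DERIVED_PATHS",
]

logger = logging.getLogger(__name__)

SUBSTATE_KEYS = tuple(s.name for s in CSE_STATES)  # CSE_OCS, CSE_HOSP_ED, CSE_HOSP

#: Derived parameter paths understood by the sensitivity analyses in addition
#: to ordinary resolvable scalars.  ``derived.cse_rr`` is the ratio of the
#: mepolizumab to the placebo annual exacerbation rate; setting it leaves the
#: placebo rate untouched and recomputes the mepolizumab rate.
DERIVED_PATHS = ("derived.cse_rr",)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AEEvent:
    """One on-treatment adverse event with trial-window incidence."""

    name: str
    trial_incidence: float  # proportion over the 52-week trial window
    cost_per_event: float  # USD
    disutility: float  # utility decrement per event

    def validate(self, path: str) -> None:
        if not 0.0 <= self.trial_incidence <= 1.0:
            raise ValidationError(f"{path}.trial_incidence not in [0, 1]")
        if self.cost_per_event < 0:
            raise ValidationError(f"{path}.cost_per_event < 0")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValidationError(f"{path}.disutility not in [0, 1]")


@dataclass
class AEProfile:
    events: list[AEEvent] = field(default_factory=list)

    def validate(self, path: str) -> None:
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            raise ValidationError(f"{path}: duplicate adverse-event names")
        for e in self.events:
            e.validate(f"{path}.{e.name}")


@dataclass
class ArmProfile:
    """One treatment arm: exacerbation rate, dosing and adverse-event burden."""

    name: str
    annual_cse_rate: float  # exacerbation events per person-year
    ae_profile: AEProfile = field(default_factory=AEProfile)
    drug_dose_mg: float = 0.0
    dosing_interval_cycles: int = 2  # dose every 4 weeks on a 2-week cycle

    def validate(self, path: str) -> None:
        if self.annual_cse_rate < 0:
            raise ValidationError(f"{path}.annual_cse_rate < 0")
        if self.drug_dose_mg < 0:
            raise ValidationError(f"{path}.drug_dose_mg < 0")
        if self.dosing_interval_cycles < 1:
            raise ValidationError(f"{path}.dosing_interval_cycles < 1")
        self.ae_profile.validate(f"{path}.ae_profile")


@dataclass
class CSESubstateSplit:
    """Mutually exclusive, exhaustive split of exacerbation events by severity.

    Proportions of events managed with oral corticosteroids only, requiring
    an ED visit (and/or a hospital contact not billed at the inpatient tier),
    and requiring inpatient hospitalisation.  Inputs that do not sum to 1 are
    renormalised on load with a logged warning.
    """

    p_ocs: float
    p_hosp_ed: float
    p_hosp: float

    def validate(self, path: str) -> None:
        for name in ("p_ocs", "p_hosp_ed", "p_hosp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{path}.{name} not in [0, 1]")
        if abs(self.p_ocs + self.p_hosp_ed + self.p_hosp - 1.0) > 1e-9:
            raise ValidationError(f"{path}: proportions must sum to 1 (after normalization)")

    @classmethod
    def normalized(cls, p_ocs: float, p_hosp_ed: float, p_hosp: float,
                   path: str = "substate_split") -> "CSESubstateSplit":
        total = p_ocs + p_hosp_ed + p_hosp
        if total <= 0:
            raise ValidationError(f"{path}: proportions sum to {total}; cannot normalize")
        if abs(total - 1.0) > 1e-9:
            logger.warning("%s: proportions sum to %.6f; renormalizing to 1", path, total)
        return cls(p_ocs / total, p_hosp_ed / total, p_hosp / total)

    def as_dict(self) -> dict[str, float]:
        return {
            "CSE_OCS": self.p_ocs,
            "CSE_HOSP_ED": self.p_hosp_ed,
            "CSE_HOSP": self.p_hosp,
        }


@dataclass
class EconomicInputs:
    """Direct and indirect (human-capital) cost inputs, USD."""

    drug_unit_price: float  # per 100 mg dose
    monitoring_cost_per_cycle: float
    cse_cost_by_substate: dict[str, float]
    daily_wage: float
    employment_rate_by_age: list[tuple[AgeBand, float]]  # sorted bands
    missed_days_outpatient: float = 1.0
    missed_days_hospitalized: float = 6.4
    presenteeism_days: float = 0.0
    exchange_rate_cny_per_usd: float = 7.0467

    def validate(self, path: str) -> None:
        for name in ("drug_unit_price", "monitoring_cost_per_cycle", "daily_wage",
                     "missed_days_outpatient", "missed_days_hospitalized",
                     "presenteeism_days"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{path}.{name} < 0")
        if self.exchange_rate_cny_per_usd <= 0:
            raise ValidationError(f"{path}.exchange_rate_cny_per_usd must be > 0")
        missing = set(SUBSTATE_KEYS) - set(self.cse_cost_by_substate)
        if missing:
            raise ValidationError(f"{path}.cse_cost_by_substate missing {sorted(missing)}")
        for k, v in self.cse_cost_by_substate.items():
            if v < 0:
                raise ValidationError(f"{path}.cse_cost_by_substate.{k} < 0")
        lows = [b[0] for b, _ in self.employment_rate_by_age]
        if lows != sorted(lows):
            raise ValidationError(f"{path}.employment_rate_by_age bands must be sorted")
        for (band, rate) in self.employment_rate_by_age:
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(
                    f"{path}.employment_rate_by_age[{band}] not in [0, 1]")

    def employment_rate(self, age: float) -> float:
        """Employment rate for the half-open band containing ``age``; 0 beyond."""
        for (low, high), rate in self.employment_rate_by_age:
            if low <= age < high:
                return rate
        return 0.0


@dataclass
class UtilityInputs:
    """Baseline utility and exacerbation / adverse-event decrements."""

    u_no_cse: float
    disutility_by_substate: dict[str, float]

    def validate(self, path: str) -> None:
        if not 0.0 <= self.u_no_cse <= 1.0:
            raise ValidationError(f"{path}.u_no_cse not in [0, 1]")
        missing = set(SUBSTATE_KEYS) - set(self.disutility_by_substate)
        if missing:
            raise ValidationError(f"{path}.disutility_by_substate missing {sorted(missing)}")
        for k, v in self.disutility_by_substate.items():
            if v < 0:
                raise ValidationError(f"{path}.disutility_by_substate.{k} < 0")


@dataclass
class DistributionSpec:
    """Sampling description for one uncertain parameter in the PSA.

    Families follow standard health-economics practice: beta for
    probabilities/proportions/utilities, gamma for costs and disutility
    magnitudes, lognormal for rate ratios; ``normal`` and ``fixed`` are
    available for symmetric perturbation studies and degenerate checks.
    """

    family: str  # beta | gamma | lognormal | normal | fixed
    params: tuple[float, ...]

    _FAMILIES = ("beta", "gamma", "lognormal", "normal", "fixed")

    def validate(self, path: str) -> None:
        if self.family not in self._FAMILIES:
            raise ValidationError(f"{path}: unknown family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValidationError(f"{path}: beta needs alpha, beta > 0")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValidationError(f"{path}: gamma needs shape, scale > 0")
        elif self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ValidationError(f"{path}: lognormal needs mu, sigma > 0")
        elif self.family == "normal":
            if len(p) != 2 or p[1] < 0:
                raise ValidationError(f"{path}: normal needs mean, sd >= 0")
        elif self.family == "fixed":
            if len(p) != 1:
                raise ValidationError(f"{path}: fixed needs a single value")

    def mean(self) -> float:
        a = self.params
        if self.family == "beta":
            return a[0] / (a[0] + a[1])
        if self.family == "gamma":
            return a[0] * a[1]
        if self.family == "lognormal":
            return math.exp(a[0] + a[1] ** 2 / 2.0)
        if self.family == "normal":
            return a[0]
        return a[0]  # fixed

    def sample(self, rng: np.random.Generator) -> float:
        a = self.params
        if self.family == "beta":
            return float(rng.beta(a[0], a[1]))
        if self.family == "gamma":
            return float(rng.gamma(a[0], a[1]))
        if self.family == "lognormal":
            return float(rng.lognormal(a[0], a[1]))
        if self.family == "normal":
            return float(rng.normal(a[0], a[1]))
        return a[0]  # fixed

    # -- moment-matching constructors ------------------------------------
    @classmethod
    def beta_from_moments(cls, mean: float, sd: float) -> "DistributionSpec":
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta mean must be in (0, 1), got {mean}")
        nu = mean * (1 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise ValidationError("beta sd too large for the mean")
        return cls("beta", (mean * nu, (1 - mean) * nu))

    @classmethod
    def gamma_from_moments(cls, mean: float, sd: float) -> "DistributionSpec":
        if mean <= 0 or sd <= 0:
            raise ValidationError("gamma moments must be positive")
        shape = (mean / sd) ** 2
        return cls("gamma", (shape, mean / shape))

    @classmethod
    def lognormal_from_ci(cls, low: float, high: float) -> "DistributionSpec":
        """Lognormal with the 95% CI (low, high) on the natural scale."""
        if not 0 < low <= high:
            raise ValidationError("lognormal CI must satisfy 0 < low <= high")
        mu = (math.log(low) + math.log(high)) / 2.0
        sigma = (math.log(high) - math.log(low)) / (2 * 1.959963984540054)
        return cls("lognormal", (mu, max(sigma, 1e-12)))


@dataclass
class ModelSettings:
    """Global run settings: cycle structure, discounting, horizon, WTP band.

    ``treatment_duration_years`` bounds the drug-dosing window (``None`` =
    dosing for life); ``ae_window_years`` bounds adverse-event cost and
    disutility accrual (``None`` = lifetime accrual, the default).  The
    exacerbation-rate benefit is held constant over the whole horizon either
    way.
    """

    cycle_length_weeks: float = 2.0
    cycles_per_year: int = 26
    annual_discount_rate: float = 0.05
    start_age: float = 52.2
    max_age: float = 100.0
    wtp_lower: float = 15217.0
    wtp_upper: float = 38042.0
    half_cycle_correction: bool = True
    treatment_duration_years: float | None = None
    ae_window_years: float | None = None

    def validate(self, path: str = "settings") -> None:
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError(f"{path}.annual_discount_rate not in [0, 1)")
        if self.cycles_per_year < 1:
            raise ValidationError(f"{path}.cycles_per_year < 1")
        if not self.start_age < self.max_age:
            raise ValidationError(f"{path}: start_age must be below max_age")
        if not self.wtp_lower < self.wtp_upper:
            raise ValidationError(f"{path}: wtp_lower must be below wtp_upper")
        for name in ("treatment_duration_years", "ae_window_years"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{path}.{name} must be positive or null")

    def on_drug(self, age: float) -> bool:
        """Whether drug acquisition cost accrues at a given cycle-start age."""
        if self.treatment_duration_years is None:
            return True
        return age < self.start_age + self.treatment_duration_years - 1e-12

    def in_ae_window(self, age: float) -> bool:
        """Whether adverse-event cost/disutility accrues at a cycle-start age."""
        if self.ae_window_years is None:
            return True
        return age < self.start_age + self.ae_window_years - 1e-12

    @property
    def cycle_years(self) -> float:
        return 1.0 / self.cycles_per_year


@dataclass
class SubgroupSpec:
    """A patient subgroup with its exacerbation rate ratio (active vs placebo)."""

    name: str
    rr: float
    rr_ci: tuple[float, float]

    def validate(self, path: str) -> None:
        if self.rr <= 0:
            raise ValidationError(f"{path}.rr must be > 0")
        low, high = self.rr_ci
        if not (0 < low <= self.rr <= high):
            raise ValidationError(f"{path}.rr_ci must satisfy low <= rr <= high, > 0")


@dataclass
class ModelParameters:
    """The complete validated parameter set for one arm-pair comparison."""

    settings: ModelSettings
    arms: tuple[ArmProfile, ArmProfile]  # (intervention, comparator)
    substate_split: CSESubstateSplit
    econ: EconomicInputs
    util: UtilityInputs
    mortality: MortalityTable
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)

    @property
    def intervention(self) -> ArmProfile:
        return self.arms[0]

    @property
    def comparator(self) -> ArmProfile:
        return self.arms[1]

    def arm(self, name: str) -> ArmProfile:
        for a in self.arms:
            if a.name == name:
                return a
        raise ValidationError(f"no arm named {name!r}")

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def validate(self) -> None:
        self.settings.validate("settings")
        if len(self.arms) != 2:
            raise ValidationError("arms: exactly two arms are required")
        if self.arms[0].name == self.arms[1].name:
            raise ValidationError("arms: arm names must differ")
        for a in self.arms:
            a.validate(f"arms.{a.name}")
        self.substate_split.validate("substate_split")
        self.econ.validate("econ")
        self.util.validate("util")
        if self.mortality.cycles_per_year != self.settings.cycles_per_year:
            raise ValidationError(
                "mortality.cycles_per_year disagrees with settings.cycles_per_year")
        for sg in self.subgroups:
            sg.validate(f"subgroups.{sg.name}")
        # every DSA/PSA path must resolve to an existing scalar (or be derived)
        for path in list(self.dsa_ranges) + list(self.psa_specs):
            if path in DERIVED_PATHS:
                continue
            value = resolve_path(self, path)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValidationError(f"{path}: does not resolve to a scalar parameter")
        for path, (low, high) in self.dsa_ranges.items():
            if low > high:
                raise ValidationError(f"dsa_ranges.{path}: low > high")
        for path, spec in self.psa_specs.items():
            spec.validate(f"psa_specs.{path}")
            point = self.point_estimate(path)
            if spec.family != "fixed" and abs(point) > 1e-12:
                rel = abs(spec.mean() - point) / abs(point)
                if rel > 0.05:
                    raise ValidationError(
                        f"psa_specs.{path}: sampling mean {spec.mean():.6g} deviates "
                        f"{rel:.1%} from the point estimate {point:.6g} (limit 5%)")

    def point_estimate(self, path: str) -> float:
        """Current value of an ordinary or derived parameter path."""
        if path == "derived.cse_rr":
            return self.intervention.annual_cse_rate / self.comparator.annual_cse_rate
        return float(resolve_path(self, path))

    def apply(self, path: str, value: float) -> None:
        """Set an ordinary or derived parameter path in place."""
        if path == "derived.cse_rr":
            self.intervention.annual_cse_rate = self.comparator.annual_cse_rate * value
        else:
            set_path(self, path, value)


# ---------------------------------------------------------------------------
# parameter paths


def _step(obj: Any, seg: str, sofar: str) -> Any:
    if isinstance(obj, dict):
        if seg in obj:
            return obj[seg]
        raise ValidationError(f"{sofar}: no key {seg!r}")
    if isinstance(obj, tuple) and obj and isinstance(obj[0], ArmProfile):
        for a in obj:
            if a.name == seg:
                return a
        raise ValidationError(f"{sofar}: no arm named {seg!r}")
    if isinstance(obj, AEProfile):
        for e in obj.events:
            if e.name == seg:
                return e
        if seg == "events":
            return obj.events
        raise ValidationError(f"{sofar}: no adverse event named {seg!r}")
    if isinstance(obj, list) and obj and isinstance(obj[0], SubgroupSpec):
        for sg in obj:
            if sg.name == seg:
                return sg
        raise ValidationError(f"{sofar}: no subgroup named {seg!r}")
    if is_dataclass(obj) and hasattr(obj, seg):
        return getattr(obj, seg)
    raise ValidationError(f"{sofar}: cannot descend into segment {seg!r}")


def resolve_path(params: ModelParameters, path: str) -> Any:
    """Resolve a dotted parameter path to its current value."""
    obj: Any = params
    sofar = ""
    for seg in path.split("."):
        obj = _step(obj, seg, sofar or "<root>")
        sofar = f"{sofar}.{seg}" if sofar else seg
    return obj


def set_path(params: ModelParameters, path: str, value: Any) -> None:
    """Assign a new value at a dotted parameter path."""
    segs = path.split(".")
    obj: Any = params
    sofar = ""
    for seg in segs[:-1]:
        obj = _step(obj, seg, sofar or "<root>")
        sofar = f"{sofar}.{seg}" if sofar else seg
    leaf = segs[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ValidationError(f"{sofar}: no key {leaf!r}")
        obj[leaf] = value
    elif is_dataclass(obj) and hasattr(obj, leaf):
        setattr(obj, leaf, value)
    else:
        raise ValidationError(f"{sofar}: cannot assign segment {leaf!r}")


def scalar_paths(params: ModelParameters) -> list[str]:
    """Enumerate the addressable scalar parameter paths of a parameter set."""
    out: list[str] = []
    for arm in params.arms:
        base = f"arms.{arm.name}"
        out += [f"{base}.annual_cse_rate", f"{base}.drug_dose_mg"]
        for e in arm.ae_profile.events:
            out += [
                f"{base}.ae_profile.{e.name}.trial_incidence",
                f"{base}.ae_profile.{e.name}.cost_per_event",
                f"{base}.ae_profile.{e.name}.disutility",
            ]
    out += ["substate_split.p_ocs", "substate_split.p_hosp_ed", "substate_split.p_hosp"]
    out += [
        "econ.drug_unit_price", "econ.monitoring_cost_per_cycle", "econ.daily_wage",
        "econ.missed_days_outpatient", "econ.missed_days_hospitalized",
        "econ.presenteeism_days",
    ]
    out += [f"econ.cse_cost_by_substate.{k}" for k in SUBSTATE_KEYS]
    out += ["util.u_no_cse"]
    out += [f"util.disutility_by_substate.{k}" for k in SUBSTATE_KEYS]
    out += ["settings.annual_discount_rate"]
    return out


# ---------------------------------------------------------------------------
# configuration IO


def _money(value: Any, fx: float, path: str) -> float:
    """A money field: plain number = USD; ``{cny: x}`` converted at ``fx``."""
    if isinstance(value, dict):
        if set(value) == {"cny"}:
            return float(value["cny"]) / fx
        raise ValidationError(f"{path}: money must be a number or {{cny: <amount>}}")
    return float(value)


def _require(d: dict, key: str, path: str) -> Any:
    if key not in d:
        raise ValidationError(f"{path}.{key}: missing required field")
    return d[key]


def _load_ae_profile(spec: Any, fx: float, path: str, base_dir: Path) -> AEProfile:
    if isinstance(spec, str):
        csv_path = (base_dir / spec).resolve()
        df = pd.read_csv(csv_path)
        logger.info("read adverse-event table %s (%d rows)", csv_path, len(df))
        rows = df.to_dict("records")
    else:
        rows = spec or []
    events = []
    for i, row in enumerate(rows):
        p = f"{path}[{i}]"
        events.append(AEEvent(
            name=str(_require(row, "name", p)),
            trial_incidence=float(_require(row, "trial_incidence", p)),
            cost_per_event=_money(_require(row, "cost_per_event", p), fx, p),
            disutility=float(_require(row, "disutility", p)),
        ))
    return AEProfile(events)


def load_parameters(source: str | Path | dict) -> ModelParameters:
    """Load and validate a full parameter set from YAML/JSON text or a dict.

    ``source`` may be a path to a YAML (or JSON, a YAML subset) file, a YAML
    string, or an already-parsed mapping.  Tabular blocks (adverse-event
    table, mortality table, subgroups) may be inlined or given as CSV paths
    relative to the config file.  Raises :class:`ValidationError` with a
    path-qualified message on any missing field or invariant violation.
    """
    base_dir = Path(".")
    if isinstance(source, dict):
        cfg = source
    else:
        text = str(source)
        if "\n" not in text:  # a path, not inline YAML text
            p = Path(source)
            if not p.exists():
                raise ValidationError(f"config file not found: {p}")
            text = p.read_text()
            base_dir = p.parent
            logger.info("read parameter config %s", p.resolve())
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError("config: top level must be a mapping")

    s = cfg.get("settings", {})
    settings = ModelSettings(
        cycle_length_weeks=float(s.get("cycle_length_weeks", 2.0)),
        cycles_per_year=int(s.get("cycles_per_year", 26)),
        annual_discount_rate=float(_require(s, "annual_discount_rate", "settings")),
        start_age=float(_require(s, "start_age", "settings")),
        max_age=float(s.get("max_age", 100.0)),
        wtp_lower=float(_require(s, "wtp_lower", "settings")),
        wtp_upper=float(_require(s, "wtp_upper", "settings")),
        half_cycle_correction=bool(s.get("half_cycle_correction", True)),
        treatment_duration_years=(
            None if s.get("treatment_duration_years") is None
            else float(s["treatment_duration_years"])),
        ae_window_years=(
            None if s.get("ae_window_years") is None
            else float(s["ae_window_years"])),
    )

    econ_cfg = _require(cfg, "econ", "<root>")
    fx = float(econ_cfg.get("exchange_rate_cny_per_usd", 7.0467))

    arms_cfg = _require(cfg, "arms", "<root>")
    if not isinstance(arms_cfg, list) or len(arms_cfg) != 2:
        raise ValidationError("arms: exactly two arm blocks are required")
    arms = []
    for a in arms_cfg:
        name = str(_require(a, "name", "arms"))
        path = f"arms.{name}"
        arms.append(ArmProfile(
            name=name,
            annual_cse_rate=float(_require(a, "annual_cse_rate", path)),
            ae_profile=_load_ae_profile(a.get("ae_profile", []), fx,
                                        f"{path}.ae_profile", base_dir),
            drug_dose_mg=float(a.get("drug_dose_mg", 0.0)),
            dosing_interval_cycles=int(a.get("dosing_interval_cycles", 2)),
        ))

    sp = _require(cfg, "substate_split", "<root>")
    split = CSESubstateSplit.normalized(
        float(_require(sp, "p_ocs", "substate_split")),
        float(_require(sp, "p_hosp_ed", "substate_split")),
        float(_require(sp, "p_hosp", "substate_split")),
    )

    emp_cfg = _require(econ_cfg, "employment_rate_by_age", "econ")
    employment = [
        ((float(r["age_low"]), float(r["age_high"])), float(r["rate"]))
        for r in emp_cfg
    ]
    cse_costs = {
        k: _money(v, fx, f"econ.cse_cost_by_substate.{k}")
        for k, v in _require(econ_cfg, "cse_cost_by_substate", "econ").items()
    }
    econ = EconomicInputs(
        drug_unit_price=_money(_require(econ_cfg, "drug_unit_price", "econ"),
                               fx, "econ.drug_unit_price"),
        monitoring_cost_per_cycle=_money(
            _require(econ_cfg, "monitoring_cost_per_cycle", "econ"),
            fx, "econ.monitoring_cost_per_cycle"),
        cse_cost_by_substate=cse_costs,
        daily_wage=_money(_require(econ_cfg, "daily_wage", "econ"),
                          fx, "econ.daily_wage"),
        employment_rate_by_age=employment,
        missed_days_outpatient=float(econ_cfg.get("missed_days_outpatient", 1.0)),
        missed_days_hospitalized=float(econ_cfg.get("missed_days_hospitalized", 6.4)),
        presenteeism_days=float(econ_cfg.get("presenteeism_days", 0.0)),
        exchange_rate_cny_per_usd=fx,
    )

    util_cfg = _require(cfg, "util", "<root>")
    util = UtilityInputs(
        u_no_cse=float(_require(util_cfg, "u_no_cse", "util")),
        disutility_by_substate={
            k: float(v)
            for k, v in _require(util_cfg, "disutility_by_substate", "util").items()
        },
    )

    mort_cfg = _require(cfg, "mortality", "<root>")
    if isinstance(mort_cfg, str):
        csv_path = (base_dir / mort_cfg).resolve()
        df = pd.read_csv(csv_path)
        logger.info("read mortality table %s (%d rows)", csv_path, len(df))
        mort_rows = df.to_dict("records")
    else:
        mort_rows = mort_cfg
    mortality = MortalityTable(
        bands=[(float(r["age_low"]), float(r["age_high"])) for r in mort_rows],
        no_cse_annual=[float(r["no_cse_annual"]) for r in mort_rows],
        cse_annual=[float(r["cse_annual"]) for r in mort_rows],
        cycles_per_year=settings.cycles_per_year,
    )

    sg_cfg = cfg.get("subgroups", [])
    if isinstance(sg_cfg, str):
        csv_path = (base_dir / sg_cfg).resolve()
        df = pd.read_csv(csv_path)
        logger.info("read subgroup table %s (%d rows)", csv_path, len(df))
        sg_cfg = df.to_dict("records")
    subgroups = [
        SubgroupSpec(name=str(r["name"]), rr=float(r["rr"]),
                     rr_ci=(float(r["ci_low"]), float(r["ci_high"])))
        for r in sg_cfg
    ]

    dsa_ranges = {
        str(k): (float(v[0]), float(v[1]))
        for k, v in cfg.get("dsa_ranges", {}).items()
    }
    psa_specs = {
        str(k): DistributionSpec(family=str(v["family"]),
                                 params=tuple(float(x) for x in v["params"]))
        for k, v in cfg.get("psa_specs", {}).items()
    }

    params = ModelParameters(
        settings=settings, arms=tuple(arms), substate_split=split,
        econ=econ, util=util, mortality=mortality, subgroups=subgroups,
        dsa_ranges=dsa_ranges, psa_specs=psa_specs,
    )
    params.validate()
    return params


def to_config(params: ModelParameters) -> dict:
    """Serialise a parameter set back to the config mapping dialect."""
    s = params.settings
    return {
        "settings": {
            "cycle_length_weeks": s.cycle_length_weeks,
            "cycles_per_year": s.cycles_per_year,
            "annual_discount_rate": s.annual_discount_rate,
            "start_age": s.start_age,
            "max_age": s.max_age,
            "wtp_lower": s.wtp_lower,
            "wtp_upper": s.wtp_upper,
            "half_cycle_correction": s.half_cycle_correction,
            "treatment_duration_years": s.treatment_duration_years,
            "ae_window_years": s.ae_window_years,
        },
        "arms": [
            {
                "name": a.name,
                "annual_cse_rate": a.annual_cse_rate,
                "drug_dose_mg": a.drug_dose_mg,
                "dosing_interval_cycles": a.dosing_interval_cycles,
                "ae_profile": [
                    {
                        "name": e.name,
                        "trial_incidence": e.trial_incidence,
                        "cost_per_event": e.cost_per_event,
                        "disutility": e.disutility,
                    }
                    for e in a.ae_profile.events
                ],
            }
            for a in params.arms
        ],
        "substate_split": {
            "p_ocs": params.substate_split.p_ocs,
            "p_hosp_ed": params.substate_split.p_hosp_ed,
            "p_hosp": params.substate_split.p_hosp,
        },
        "econ": {
            "drug_unit_price": params.econ.drug_unit_price,
            "monitoring_cost_per_cycle": params.econ.monitoring_cost_per_cycle,
            "cse_cost_by_substate": dict(params.econ.cse_cost_by_substate),
            "daily_wage": params.econ.daily_wage,
            "employment_rate_by_age": [
                {"age_low": b[0], "age_high": b[1], "rate": r}
                for b, r in params.econ.employment_rate_by_age
            ],
            "missed_days_outpatient": params.econ.missed_days_outpatient,
            "missed_days_hospitalized": params.econ.missed_days_hospitalized,
            "presenteeism_days": params.econ.presenteeism_days,
            "exchange_rate_cny_per_usd": params.econ.exchange_rate_cny_per_usd,
        },
        "util": {
            "u_no_cse": params.util.u_no_cse,
            "disutility_by_substate": dict(params.util.disutility_by_substate),
        },
        "mortality": [
            {
                "age_low": b[0], "age_high": b[1],
                "no_cse_annual": p0, "cse_annual": p1,
            }
            for b, p0, p1 in zip(params.mortality.bands,
                                 params.mortality.no_cse_annual,
                                 params.mortality.cse_annual)
        ],
        "subgroups": [
            {"name": sg.name, "rr": sg.rr,
             "ci_low": sg.rr_ci[0], "ci_high": sg.rr_ci[1]}
            for sg in params.subgroups
        ],
        "dsa_ranges": {k: [v[0], v[1]] for k, v in params.dsa_ranges.items()},
        "psa_specs": {
            k: {"family": v.family, "params": list(v.params)}
            for k, v in params.psa_specs.items()
        },
    }

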