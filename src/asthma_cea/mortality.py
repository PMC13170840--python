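"""Age-specific asthma mortality: stepwise derivation and state-specific lookup.

Annual asthma mortality among patients without a current exacerbation is
derived by combining three tables — asthma deaths, asthma incidence rates and
population counts, each stratified by age band and gender:

1. per (band, gender): ``rate = deaths / (incidence * population)``, i.e.
   deaths among prevalent cases approximated by incidence-derived case counts;
2. per band: the gender-specific rates are averaged with weights equal to the
   gender-specific population sizes.

Mortality during an exacerbation cycle comes from its own age-indexed table
(observational estimates of exacerbation-related death), independent of the
derivation above.  Annual probabilities are converted to per-cycle
probabilities with the compound formula ``1 - (1 - p)**(1/cycles_per_year)``.

Age bands are half-open ``[low, high)``; the final band is open-ended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .conversions import ValidationError, annual_prob_to_cycle
from .states import CSE_STATES, HealthState

logger = logging.getLogger(__name__)

AgeBand = tuple[float, float]


def _band_index(bands: list[AgeBand], age: float) -> int:
    """Index of the half-open band containing ``age``; last band open-ended."""
    for i, (low, high) in enumerate(bands):
        is_last = i == len(bands) - 1
        if low <= age and (age < high or is_last):
            return i
    raise ValidationError(f"age {age} is outside mortality table coverage "
                          f"[{bands[0][0]}, ...)")


@dataclass
class MortalityInputs:
    """The three source tables of the stepwise mortality derivation.

    Each mapping is keyed by ``(age_band, gender)`` with ``age_band`` a
    ``(low, high)`` tuple.  ``incidence`` values are rates per person in
    [0, 1]; ``deaths`` and ``population`` are non-negative counts.
    """

    deaths: dict[tuple[AgeBand, str], float]
    incidence: dict[tuple[AgeBand, str], float]
    population: dict[tuple[AgeBand, str], float]

    def __post_init__(self) -> None:
        keys = set(self.deaths)
        if set(self.incidence) != keys or set(self.population) != keys:
            raise ValidationError(
                "mortality inputs: deaths/incidence/population must share "
                "identical (age band, gender) keys"
            )
        for k, v in self.deaths.items():
            if v < 0:
                raise ValidationError(f"mortality inputs: deaths[{k}] < 0")
        for k, v in self.incidence.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"mortality inputs: incidence[{k}] not in [0, 1]")
        for k, v in self.population.items():
            if v < 0:
                raise ValidationError(f"mortality inputs: population[{k}] < 0")

    @property
    def bands(self) -> list[AgeBand]:
        return sorted({band for band, _ in self.deaths})

    @property
    def genders(self) -> list[str]:
        return sorted({g for _, g in self.deaths})


def derive_mortality_table(inputs: MortalityInputs) -> dict[AgeBand, float]:
    """Derive gender-aggregated annual asthma mortality per age band.

    Per gender the rate is deaths over estimated asthma cases
    (incidence x population); per band the gender rates are weighted by the
    gender-specific population sizes.  Results are clamped to [0, 1] with a
    warning.
    """
    out: dict[AgeBand, float] = {}
    for band in inputs.bands:
        num = 0.0
        den = 0.0
        for gender in inputs.genders:
            key = (band, gender)
            deaths = inputs.deaths[key]
            cases = inputs.incidence[key] * inputs.population[key]
            if cases <= 0:
                if deaths > 0:
                    raise ValidationError(
                        f"band {band}, gender {gender!r}: {deaths} deaths but "
                        "zero estimated asthma cases (incidence x population)"
                    )
                rate_g = 0.0
            else:
                rate_g = deaths / cases
            pop = inputs.population[key]
            num += rate_g * pop
            den += pop
        rate = num / den if den > 0 else 0.0
        if rate > 1.0:
            logger.warning("band %s: derived mortality %.4f > 1; clamping", band, rate)
            rate = 1.0
        out[band] = rate
    return out


@dataclass
class MortalityTable:
    """Age-indexed annual and per-cycle asthma death probabilities by state.

    ``no_cse_annual[i]`` / ``cse_annual[i]`` apply over ``bands[i]``; an
    exacerbation must not lower the risk of death, so ``cse >= no_cse`` per
    band.  Per-cycle values are derived with the compound conversion and
    cached.
    """

    bands: list[AgeBand]
    no_cse_annual: list[float]
    cse_annual: list[float]
    cycles_per_year: int = 26
    no_cse_cycle: list[float] = field(init=False, repr=False)
    cse_cycle: list[float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.bands)
        if len(self.no_cse_annual) != n or len(self.cse_annual) != n:
            raise ValidationError("mortality: bands and rate lists differ in length")
        if n == 0:
            raise ValidationError("mortality: empty table")
        lows = [b[0] for b in self.bands]
        if lows != sorted(lows):
            raise ValidationError("mortality: bands must be sorted by age")
        for i, (p0, p1) in enumerate(zip(self.no_cse_annual, self.cse_annual)):
            path = f"mortality.bands[{i}]={self.bands[i]}"
            if not 0.0 <= p0 <= 1.0 or not 0.0 <= p1 <= 1.0:
                raise ValidationError(f"{path}: annual probabilities must be in [0, 1]")
            if p1 < p0:
                raise ValidationError(
                    f"{path}: CSE mortality {p1} below no-CSE mortality {p0}"
                )
        self.no_cse_cycle = [
            annual_prob_to_cycle(p, self.cycles_per_year) for p in self.no_cse_annual
        ]
        self.cse_cycle = [
            annual_prob_to_cycle(p, self.cycles_per_year) for p in self.cse_annual
        ]

    # equality ignores the derived caches' float identity (they are functions
    # of the annual values), so the default dataclass __eq__ is fine.

    def annual_at(self, state: HealthState, age: float) -> float:
        i = _band_index(self.bands, age)
        if state == HealthState.NO_CSE:
            return self.no_cse_annual[i]
        if state in CSE_STATES:
            return self.cse_annual[i]
        raise ValidationError(f"no mortality defined for state {state.name}")

    def cycle_at(self, state: HealthState, age: float) -> float:
        i = _band_index(self.bands, age)
        if state == HealthState.NO_CSE:
            return self.no_cse_cycle[i]
        if state in CSE_STATES:
            return self.cse_cycle[i]
        raise ValidationError(f"no mortality defined for state {state.name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_low": [b[0] for b in self.bands],
                "age_high": [b[1] for b in self.bands],
                "no_cse_annual": self.no_cse_annual,
                "cse_annual": self.cse_annual,
                "no_cse_cycle": self.no_cse_cycle,
                "cse_cycle": self.cse_cycle,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        logger.info("wrote mortality table to %s (%d bands)",
                    path.resolve(), len(self.bands))


def lookup_cycle_mortality(table: MortalityTable, state: HealthState, age: float) -> float:
    """Per-cycle death probability for a living state at an age.

    All CSE substates share the exacerbation mortality channel; the lookup
    uses the half-open band containing ``age``.
    """
    return table.cycle_at(state, age)


def read_mortality_inputs_csv(
    deaths_csv: str | Path,
    incidence_csv: str | Path,
    population_csv: str | Path,
) -> MortalityInputs:
    """Read the three source tables from CSV (age_low, age_high, gender, value)."""

    def _read(path: str | Path) -> dict[tuple[AgeBand, str], float]:
        path = Path(path)
        df = pd.read_csv(path)
        logger.info("read %s (%d rows)", path.resolve(), len(df))
        return {
            ((float(r.age_low), float(r.age_high)), str(r.gender)): float(r.value)
            for r in df.itertuples()
        }

    return MortalityInputs(
        deaths=_read(deaths_csv),
        incidence=_read(incidence_csv),
        population=_read(population_csv),
    )
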