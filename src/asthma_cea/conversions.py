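"""Rate, probability and discount conversions between annual and cycle scales.

Two distinct conversions are used, fixed per parameter class:

* Event *rates* (exacerbations per person-year) are divided by the number of
  cycles per year.  The quotient is used directly as the per-cycle
  probability of an exacerbation cycle, clamped at 1 with a warning if an
  extreme input pushes it past certainty.
* Mortality *probabilities* use the compound-interest form
  ``1 - (1 - p_annual)**(1/cycles_per_year)``, so that compounding the
  per-cycle probability over a year recovers the annual probability exactly.

Discounting is annual, applied per cycle as ``(1+r)**(-k/cycles_per_year)``.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a model contract; message names the path."""


def annual_event_rate_to_cycle(rate_annual: float, cycles_per_year: int = 26) -> float:
    """Convert an annual event rate to a per-cycle event probability.

    Straight division by the number of cycles per year: an annual rate of
    1.31 events/person-year on a 2-week cycle gives 0.05038 per cycle.
    The result is clamped to at most 1 (with a warning), since it is
    consumed as a probability of at least one exacerbation in the cycle.

    Parameters
    ----------
    rate_annual:
        Events per person-year, >= 0.
    cycles_per_year:
        Number of model cycles in one year (26 for a 2-week cycle).
    """
    if rate_annual < 0:
        raise ValidationError(f"annual event rate must be >= 0, got {rate_annual}")
    if cycles_per_year < 1:
        raise ValidationError(f"cycles_per_year must be >= 1, got {cycles_per_year}")
    rate = rate_annual / cycles_per_year
    if rate > 1.0:
        logger.warning(
            "per-cycle event rate %.4f exceeds 1; clamping to 1 "
            "(annual rate %.4f over %d cycles/year)",
            rate, rate_annual, cycles_per_year,
        )
        rate = 1.0
    return rate


def annual_prob_to_cycle(p_annual: float, cycles_per_year: int = 26) -> float:
    """Convert an annual probability to a per-cycle probability.

    Uses ``1 - (1 - p)**(1/cycles_per_year)``; compounding the result over
    ``cycles_per_year`` cycles recovers ``p_annual``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValidationError(f"annual probability must be in [0, 1], got {p_annual}")
    if cycles_per_year < 1:
        raise ValidationError(f"cycles_per_year must be >= 1, got {cycles_per_year}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def cycle_prob_to_annual(p_cycle: float, cycles_per_year: int = 26) -> float:
    """Inverse of :func:`annual_prob_to_cycle` (compound over one year)."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValidationError(f"cycle probability must be in [0, 1], got {p_cycle}")
    return 1.0 - (1.0 - p_cycle) ** cycles_per_year


def per_cycle_discount_factor(
    cycle_index: float,
    annual_discount_rate: float = 0.05,
    cycles_per_year: int = 26,
) -> float:
    """Discount factor applied at a given cycle index.

    ``(1 + r)**(-k / cycles_per_year)``: 1 at cycle 0, ``1/(1+r)`` after one
    full year of cycles.
    """
    if cycle_index < 0:
        raise ValidationError(f"cycle_index must be >= 0, got {cycle_index}")
    return (1.0 + annual_discount_rate) ** (-cycle_index / cycles_per_year)
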