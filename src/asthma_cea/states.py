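"""Health-state enumeration shared across the model.

The cohort moves between a stable state with no clinically significant
exacerbation (CSE), three one-cycle CSE severity substates distinguished by
the resources used to manage the event, and an absorbing death state.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """States of the 2-week-cycle Markov model.

    ``NO_CSE``      stable severe asthma on maintenance therapy.
    ``CSE_OCS``     exacerbation managed with an oral corticosteroid burst.
    ``CSE_HOSP_ED`` exacerbation needing hospitalisation and/or an ED visit.
    ``CSE_HOSP``    exacerbation needing inpatient hospitalisation.
    ``DEATH``       absorbing.

    The three CSE states are tunnel states: they are entered only from
    ``NO_CSE`` and exited within one cycle (back to ``NO_CSE`` or to
    ``DEATH``).
    """

    NO_CSE = 0
    CSE_OCS = 1
    CSE_HOSP_ED = 2
    CSE_HOSP = 3
    DEATH = 4


#: The three exacerbation tunnel states, in index order.
CSE_STATES: tuple[HealthState, ...] = (
    HealthState.CSE_OCS,
    HealthState.CSE_HOSP_ED,
    HealthState.CSE_HOSP,
)

#: States in which the cohort is alive.
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.NO_CSE,
    HealthState.CSE_OCS,
    HealthState.CSE_HOSP_ED,
    HealthState.CSE_HOSP,
)

N_STATES: int = len(HealthState)
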