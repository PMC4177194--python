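"""Shared event vocabulary and the timestamped event log record.

Every observable thing that happens to a simulated patient is logged as an
:class:`EventRecord`; costs and all reported outcomes are computed from this
log alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

# Outpatient cycle outcomes (conventional arm)
NONE = "none"
MEDICATION_CHANGE = "medication_change"
GP_VISIT = "gp_visit"
SPECIALIST_VISIT = "specialist_visit"
AMBULANCE_VISIT = "ambulance_visit"
EMERGENCY_ADMISSION = "emergency_admission"
REFERRAL_ADMISSION = "referral_admission"
EXTRAMURAL_DEATH = "extramural_death"

# Telemedical cycle outcomes (in addition to the shared kinds above)
INTERVENTION = "intervention"
HOME_VISIT = "home_visit"
DOCTOR_VISIT = "doctor_visit"

# Inpatient stream events
WARD_STAY = "ward_stay"
ICU_STAY = "icu_stay"
IMP = "imp"
DISCHARGE = "discharge"
IN_HOSPITAL_DEATH = "in_hospital_death"

OUTPATIENT_KINDS = frozenset(
    {
        NONE,
        MEDICATION_CHANGE,
        GP_VISIT,
        SPECIALIST_VISIT,
        AMBULANCE_VISIT,
        EMERGENCY_ADMISSION,
        REFERRAL_ADMISSION,
        EXTRAMURAL_DEATH,
    }
)

TELEMED_KINDS = frozenset(
    {
        NONE,
        INTERVENTION,
        HOME_VISIT,
        DOCTOR_VISIT,
        EMERGENCY_ADMISSION,
        REFERRAL_ADMISSION,
        EXTRAMURAL_DEATH,
    }
)

ADMISSION_KINDS = frozenset({EMERGENCY_ADMISSION, REFERRAL_ADMISSION})

INPATIENT_KINDS = frozenset({WARD_STAY, ICU_STAY, IMP, DISCHARGE, IN_HOSPITAL_DEATH})

ALL_KINDS = OUTPATIENT_KINDS | TELEMED_KINDS | INPATIENT_KINDS


class StateError(RuntimeError):
    """A pathway operation was invoked on a patient in an incompatible state."""


@dataclass(frozen=True)
class EventRecord:
    """One timestamped entry in a run's event log."""

    day: int
    patient_id: int
    kind: str
    payload: Any = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
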