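"""Telemedical-arm outpatient care: the weekly telemonitoring control cycle.

Monitored patients transmit vital data (weight, blood pressure, heart rate,
medication) daily; the transmissions themselves are cost-free bookkeeping —
system costs enter through the financing block of the scenario.  Clinical
branching happens once per week, when the telemedicine centre reviews the
data: an alarm can trigger an emergency admission, a successful remote
intervention (e.g. medication adjustment), or a face-to-face contact (home
visit, doctor visit, or direct hospitalisation).  A face-to-face contact
that fails to stabilise the patient can end in extramural death (when
enabled) or a referral admission, mirroring the conventional pathway.

After an alarm cycle that did not end in admission or death the patient's
NYHA class may change, using the same (improve, stay, worsen) triple as the
post-discharge transition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import NyhaParameters, Toggles
from .conventional import schedule_routine_visits
from .events import (
    DOCTOR_VISIT,
    EMERGENCY_ADMISSION,
    EXTRAMURAL_DEATH,
    HOME_VISIT,
    INTERVENTION,
    NONE,
    REFERRAL_ADMISSION,
    StateError,
)
from .kernels import RngStream, draw_bernoulli, draw_categorical, sample_nyha_transition

__all__ = [
    "CONTROL_CYCLE_DAYS",
    "TelemedOutcome",
    "is_control_day",
    "telemedical_control_cycle",
    "telemedical_routine_visits",
]

CONTROL_CYCLE_DAYS = 7

_TERMINAL = (EMERGENCY_ADMISSION, REFERRAL_ADMISSION, EXTRAMURAL_DEATH)


@dataclass(frozen=True)
class TelemedOutcome:
    """The single outcome of one weekly control cycle."""

    kind: str
    day: int


def is_control_day(day: int) -> bool:
    """True on control-cycle days: every 7th day, i.e. days 6, 13, 20, ...

    A horizon of ``H`` days therefore contains exactly ``H // 7`` control
    cycles for a continuously outpatient patient.
    """
    return (day + 1) % CONTROL_CYCLE_DAYS == 0


def telemedical_control_cycle(
    patient,
    params: NyhaParameters,
    toggles: Toggles,
    rng: RngStream,
    day: int = CONTROL_CYCLE_DAYS - 1,
) -> TelemedOutcome:
    """Run one weekly control cycle for an alive, monitored outpatient.

    May update ``patient.nyha`` in place (alarm cycles resolved outside
    hospital apply the severity-transition draw directly; admissions get
    their transition at discharge instead).
    """
    if getattr(patient, "status", "outpatient") != "outpatient":
        raise StateError(
            f"patient {patient.id} is {patient.status}, not in outpatient care"
        )
    if not is_control_day(day):
        raise StateError(f"day {day} is not a control-cycle day")

    if not draw_bernoulli(params.tm_alarm_prob_per_cycle, rng):
        return TelemedOutcome(NONE, day)

    if draw_bernoulli(params.emergency_prob_given_worsening, rng):
        return TelemedOutcome(EMERGENCY_ADMISSION, day)

    if draw_bernoulli(params.tm_intervention_success_prob, rng):
        outcome = TelemedOutcome(INTERVENTION, day)
    else:
        idx = draw_categorical(params.tm_contact_choice_probs, rng)
        if idx == 2:
            return TelemedOutcome(REFERRAL_ADMISSION, day)
        contact = (HOME_VISIT, DOCTOR_VISIT)[idx]
        if draw_bernoulli(params.tm_facetoface_adaptation_prob, rng):
            outcome = TelemedOutcome(contact, day)
        elif toggles.extramural_mortality and draw_bernoulli(
            params.extramural_mortality_prob, rng
        ):
            return TelemedOutcome(EXTRAMURAL_DEATH, day)
        elif draw_bernoulli(params.hospitalization_prob_no_improvement, rng):
            return TelemedOutcome(REFERRAL_ADMISSION, day)
        else:
            outcome = TelemedOutcome(contact, day)

    # Severity may shift after an alarm handled outside the hospital.
    patient.nyha = sample_nyha_transition(
        patient.nyha, params.discharge_transition_probs, rng
    )
    return outcome


def telemedical_routine_visits(
    params: NyhaParameters, horizon_days: int, rng: RngStream
) -> list:
    """Routine GP/specialist visit schedule at the telemedical-arm rates."""
    return schedule_routine_visits(params, horizon_days, rng)
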