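"""Conventional-arm outpatient care: the daily decline-and-response cycle.

Each outpatient day one cycle runs: a possible worsening of the health
state, then either an emergency transport to hospital or a response chosen
among a medication change (no personal contact) and a contact with one of
three providers (general practitioner, specialist, ambulance).  If the
contact does not improve the state, the patient may die extramurally (when
that outcome is enabled), be referred to hospital, or simply carry the
contact over to the next day's cycle.  Routine, non-worsening-triggered GP
and specialist visits are scheduled separately as a Poisson process.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import NyhaParameters, Toggles
from .events import (
    AMBULANCE_VISIT,
    EMERGENCY_ADMISSION,
    EXTRAMURAL_DEATH,
    GP_VISIT,
    MEDICATION_CHANGE,
    NONE,
    REFERRAL_ADMISSION,
    SPECIALIST_VISIT,
    StateError,
)
from .kernels import RngStream, draw_bernoulli, draw_categorical

__all__ = ["OutpatientOutcome", "conventional_daily_cycle", "schedule_routine_visits", "DAYS_PER_YEAR"]

DAYS_PER_YEAR = 365.25

# Order matches the (medication, doctor, specialist, ambulance) branch draw.
_CONTACT_KINDS = (MEDICATION_CHANGE, GP_VISIT, SPECIALIST_VISIT, AMBULANCE_VISIT)


@dataclass(frozen=True)
class OutpatientOutcome:
    """The single outcome of one patient-day outpatient cycle."""

    kind: str
    day: int


def conventional_daily_cycle(
    patient,
    params: NyhaParameters,
    toggles: Toggles,
    rng: RngStream,
    day: int = 0,
) -> OutpatientOutcome:
    """Run one conventional-arm outpatient day for an alive outpatient.

    The unbounded no-improvement loop of the care pathway is resolved within
    a single day: one contact, one improvement check, then death / referral /
    carry-over — consistent with the one-day time step.
    """
    if getattr(patient, "status", "outpatient") != "outpatient":
        raise StateError(
            f"patient {patient.id} is {patient.status}, not in outpatient care"
        )

    if not draw_bernoulli(params.worsening_prob_per_day, rng):
        return OutpatientOutcome(NONE, day)
    if draw_bernoulli(params.emergency_prob_given_worsening, rng):
        return OutpatientOutcome(EMERGENCY_ADMISSION, day)

    idx = draw_categorical(
        (params.medication_change_prob, *params.provider_choice_probs), rng
    )
    contact = _CONTACT_KINDS[idx]

    if draw_bernoulli(params.improvement_prob_after_contact, rng):
        return OutpatientOutcome(contact, day)
    if toggles.extramural_mortality and draw_bernoulli(
        params.extramural_mortality_prob, rng
    ):
        return OutpatientOutcome(EXTRAMURAL_DEATH, day)
    if draw_bernoulli(params.hospitalization_prob_no_improvement, rng):
        return OutpatientOutcome(REFERRAL_ADMISSION, day)
    return OutpatientOutcome(contact, day)


def schedule_routine_visits(
    params: NyhaParameters, horizon_days: int, rng: RngStream
) -> list:
    """Pre-draw routine GP and specialist visit days over the horizon.

    Visits arrive as homogeneous Poisson processes at ``gp_visits_per_year``
    and ``specialist_visits_per_year`` (year = 365.25 days), independent of
    the worsening-triggered contacts.  Returns a day-sorted list of
    ``(day, kind)`` pairs with kinds ``gp_visit`` / ``specialist_visit``.
    """
    if horizon_days < 0:
        raise ValueError("horizon_days must be >= 0")
    gen = rng.generator
    visits = []
    for rate, kind in (
        (params.gp_visits_per_year, GP_VISIT),
        (params.specialist_visits_per_year, SPECIALIST_VISIT),
    ):
        if rate < 0:
            raise ValueError("visit rates must be nonnegative")
        n = int(gen.poisson(rate * horizon_days / DAYS_PER_YEAR))
        days = (gen.random(n) * horizon_days).astype(int)
        visits.extend((int(d), kind) for d in days)
    visits.sort(key=lambda pair: pair[0])
    return visits
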