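"""Inpatient care: ward/ICU stays, procedures, in-hospital mortality, discharge.

A hospital admission is resolved in one shot when the patient arrives: ICU
involvement, lengths of stay, individual medical procedures (IMPs), survival
and — on survival — the post-discharge NYHA class are all drawn up front and
recorded in an :class:`AdmissionRecord`.  The record is equivalent, in cost
and outcome terms, to stepping the patient day by day between ward and ICU:
the reimbursement scheme needs only day counts, and the model ties no other
decision to the within-stay ordering.

ICU days, when they occur, are placed at the start of the stay (acute
decompensation first, step-down to the ward afterwards); this matters only
when an in-hospital death truncates the stay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import NyhaParameters
from .events import (
    DISCHARGE,
    ICU_STAY,
    IMP,
    IN_HOSPITAL_DEATH,
    WARD_STAY,
    EventRecord,
    StateError,
)
from .kernels import (
    RngStream,
    draw_bernoulli,
    draw_categorical,
    sample_los,
    sample_nyha_transition,
)

__all__ = ["AdmissionRecord", "run_admission", "admission_event_stream"]


@dataclass
class AdmissionRecord:
    """Everything that happened during one hospital admission."""

    patient_id: int
    admit_day: int
    ward_days: int
    icu_days: int
    imp_codes: list
    died_in_hospital: bool
    nyha_at_admit: int
    nyha_at_discharge: Optional[int] = None
    discharge_day: Optional[int] = None

    @property
    def total_days(self) -> int:
        return self.ward_days + self.icu_days

    @property
    def end_day(self) -> int:
        """Day the stay ends (discharge day, or death day for fatal stays)."""
        return self.admit_day + self.total_days


def run_admission(
    patient,
    params: NyhaParameters,
    rng: RngStream,
    admit_day: int = 0,
    los_dispersion: float = 0.5,
) -> AdmissionRecord:
    """Resolve one hospital admission for an alive patient.

    Draws, in fixed order: ICU involvement (``icu_admission_prob``), the ward
    stay (log-normal around ``los_ward_median_days``), the ICU stay when ICU
    care occurs, one IMP (``imp_prob`` then ``imp_weights``), and survival
    (``in_hospital_mortality_prob``).  A death truncates the stay at a day
    drawn uniformly within the sampled total stay; survivors get their
    discharge NYHA class from the (improve, stay, worsen) transition triple.
    """
    if getattr(patient, "status", None) == "dead":
        raise StateError(f"patient {patient.id} is dead and cannot be admitted")

    icu = draw_bernoulli(params.icu_admission_prob, rng)
    ward_days = sample_los(params.los_ward_median_days, los_dispersion, rng)
    icu_days = (
        sample_los(params.los_icu_median_days, los_dispersion, rng) if icu else 0
    )

    imp_codes: list = []
    if draw_bernoulli(params.imp_prob, rng):
        codes = list(params.imp_weights)
        weights = [params.imp_weights[c] for c in codes]
        imp_codes.append(codes[draw_categorical(weights, rng)])

    died = draw_bernoulli(params.in_hospital_mortality_prob, rng)
    total = ward_days + icu_days
    if died:
        death_on = 1 + int(rng.random() * total)  # uniform over days 1..total
        icu_accrued = min(icu_days, death_on)  # ICU days lead the stay
        return AdmissionRecord(
            patient_id=patient.id,
            admit_day=admit_day,
            ward_days=death_on - icu_accrued,
            icu_days=icu_accrued,
            imp_codes=imp_codes,
            died_in_hospital=True,
            nyha_at_admit=patient.nyha,
        )

    nyha_out = sample_nyha_transition(
        patient.nyha, params.discharge_transition_probs, rng
    )
    return AdmissionRecord(
        patient_id=patient.id,
        admit_day=admit_day,
        ward_days=ward_days,
        icu_days=icu_days,
        imp_codes=imp_codes,
        died_in_hospital=False,
        nyha_at_admit=patient.nyha,
        nyha_at_discharge=nyha_out,
        discharge_day=admit_day + total,
    )


def admission_event_stream(record: AdmissionRecord) -> list:
    """Expand a completed admission into day-stamped log events.

    One ward-stay event, an ICU event when ICU days accrued, one event per
    procedure, and a terminal discharge or in-hospital-death event at the day
    the stay ended.  Feeds the cost engine, which prices stays from the day
    counts carried in the payloads.
    """
    events = [
        EventRecord(
            day=record.admit_day,
            patient_id=record.patient_id,
            kind=WARD_STAY,
            payload={"days": record.ward_days},
        )
    ]
    if record.icu_days > 0:
        events.append(
            EventRecord(
                day=record.admit_day,
                patient_id=record.patient_id,
                kind=ICU_STAY,
                payload={"days": record.icu_days},
            )
        )
    for code in record.imp_codes:
        events.append(
            EventRecord(
                day=record.admit_day,
                patient_id=record.patient_id,
                kind=IMP,
                payload={"code": code},
            )
        )
    terminal = IN_HOSPITAL_DEATH if record.died_in_hospital else DISCHARGE
    events.append(
        EventRecord(day=record.end_day, patient_id=record.patient_id, kind=terminal)
    )
    return events
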