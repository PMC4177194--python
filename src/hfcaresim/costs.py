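"""The cost engine: event streams to euro amounts.

Inpatient stays are priced under an LDF-style case-flat-rate scheme: a stay
whose total length lies between the trim points earns the group's flat point
score; days beyond the upper trim point earn daily supplements; stays below
the lower trim point earn a reduced flat rate.  ICU days earn a daily
supplementary score on top, and individual medical procedures add their
catalogue points.  Points convert to euros through the adjustable
euro-per-point factor.  Outpatient events are priced at fixed tariffs,
subject to the scenario's cost toggles.  Telemonitoring system costs follow
one of two financing variants (flat per-patient monthly rate, or split
acquisition / overhead / physician fee).

All amounts are computed and accumulated in integer euro cents so that
category subtotals add up exactly; conversion to euros happens only at the
reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .config import CostTariffs, LdfGroup, TelemedFinancing, Toggles
from . import events as ev
from .inpatient import AdmissionRecord

__all__ = [
    "CATEGORY_WARD",
    "CATEGORY_ICU",
    "CATEGORY_IMP",
    "CATEGORY_OUTPATIENT",
    "CATEGORY_TELEMED",
    "CATEGORIES",
    "CostLine",
    "cents",
    "eur",
    "ldf_reimbursement",
    "icu_supplement",
    "imp_cost",
    "outpatient_event_cost",
    "telemed_system_cost",
    "admission_total_cost",
]

CATEGORY_WARD = "ward"
CATEGORY_ICU = "icu"
CATEGORY_IMP = "imp"
CATEGORY_OUTPATIENT = "outpatient_standard"
CATEGORY_TELEMED = "telemed_system"
CATEGORIES = (
    CATEGORY_WARD,
    CATEGORY_ICU,
    CATEGORY_IMP,
    CATEGORY_OUTPATIENT,
    CATEGORY_TELEMED,
)


def cents(amount_eur: float) -> int:
    """Euros to integer cents (round half away from zero is not needed here:
    all tariff inputs are cent-resolved)."""
    return round(amount_eur * 100)


def eur(amount_cents: int) -> float:
    """Integer cents to euros."""
    return amount_cents / 100.0


@dataclass(frozen=True)
class CostLine:
    """One booked amount: day, category, cents, and who it is attached to.

    ``patient_id is None`` marks a cohort-level line (e.g. the variant-B
    monthly service overhead, which is one contract for the whole cohort).
    """

    day: int
    category: str
    amount_cents: int
    patient_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        if self.amount_cents < 0:
            raise ValueError("cost lines must be nonnegative")


def ldf_reimbursement(los_days: int, ldf: LdfGroup, euro_per_point: float) -> int:
    """Case-flat-rate reimbursement (cents) for a stay of ``los_days`` days.

    Within trim points: the flat score.  Beyond the upper trim point: flat
    score plus one daily supplement per extra day.  Below the lower trim
    point: the reduced flat rate.
    """
    if los_days < 1:
        raise ValueError(f"length of stay must be >= 1 day, got {los_days}")
    if los_days < ldf.trim_min_days:
        points = ldf.flat_points * ldf.reduced_flat_fraction
    elif los_days <= ldf.trim_max_days:
        points = ldf.flat_points
    else:
        points = ldf.flat_points + (los_days - ldf.trim_max_days) * ldf.daily_supplement_points
    return cents(points * euro_per_point)


def icu_supplement(icu_days: int, ldf: LdfGroup, euro_per_point: float) -> int:
    """Daily ICU supplementary score for ``icu_days`` days, in cents."""
    if icu_days < 0:
        raise ValueError("icu_days must be >= 0")
    return cents(icu_days * ldf.icu_daily_supplement_points * euro_per_point)


def imp_cost(codes: Sequence[str], catalogue, euro_per_point: float) -> int:
    """Procedure components for the given catalogue codes, in cents.

    Repeated codes are allowed (repeat procedures) and priced each time.
    """
    by_code = {e.code: e.points for e in catalogue}
    total = 0.0
    for code in codes:
        if code not in by_code:
            raise KeyError(f"IMP code {code!r} not in catalogue")
        total += by_code[code]
    return cents(total * euro_per_point)


def outpatient_event_cost(kind: str, tariffs: CostTariffs, toggles: Toggles) -> int:
    """Tariff (cents) for one outpatient event kind, honouring the toggles.

    Ambulance visits, medication changes and emergency transports cost
    nothing when their toggle is off; admissions themselves are priced by
    the inpatient side; telemedical remote interventions are free (system
    costs are booked through the financing block).
    """
    if kind in (ev.GP_VISIT, ev.DOCTOR_VISIT):
        return cents(tariffs.gp_visit_eur)
    if kind == ev.SPECIALIST_VISIT:
        return cents(tariffs.specialist_visit_eur)
    if kind == ev.HOME_VISIT:
        return cents(tariffs.home_visit_eur)
    if kind == ev.AMBULANCE_VISIT:
        return cents(tariffs.ambulance_visit_eur) if toggles.ambulance_costs else 0
    if kind == ev.MEDICATION_CHANGE:
        return cents(tariffs.medication_event_eur) if toggles.medication_costs else 0
    if kind == ev.EMERGENCY_ADMISSION:
        return cents(tariffs.emergency_transport_eur) if toggles.transport_costs else 0
    if kind in (ev.NONE, ev.INTERVENTION, ev.REFERRAL_ADMISSION, ev.EXTRAMURAL_DEATH):
        return 0
    raise ValueError(f"unknown outpatient event kind {kind!r}")


def telemed_system_cost(
    financing: Optional[TelemedFinancing],
    n_patients: int,
    elapsed_months: int,
    month_days: float = 30.4375,
) -> list:
    """System cost lines for a fully monitored cohort over whole months.

    Variant A: one line per patient per month at the flat monthly rate.
    Variant B: one acquisition line per patient system at month 0, one
    cohort-level overhead line per month, and one physician-fee line per
    patient per month.  Lines are day-stamped at the end of the month they
    pay for.  This is the no-attrition closed form; the simulation engine
    books the same per-month charges but skips patients who have died.
    """
    if financing is None:
        raise ValueError("telemedical arm requires a financing configuration")
    if elapsed_months < 0:
        raise ValueError("elapsed_months must be >= 0")
    lines: list = []
    if financing.variant == "A":
        rate = cents(financing.monthly_rate_per_patient_eur)
        for m in range(1, elapsed_months + 1):
            day = int(m * month_days) - 1
            lines.extend(
                CostLine(day, CATEGORY_TELEMED, rate, pid) for pid in range(n_patients)
            )
        return lines
    if financing.variant != "B":
        raise ValueError(f"unknown financing variant {financing.variant!r}")
    acq = cents(financing.acquisition_per_system_eur)
    overhead = cents(financing.monthly_overhead_eur)
    fee = cents(financing.physician_fee_per_patient_month_eur)
    lines.extend(CostLine(0, CATEGORY_TELEMED, acq, pid) for pid in range(n_patients))
    for m in range(1, elapsed_months + 1):
        day = int(m * month_days) - 1
        lines.append(CostLine(day, CATEGORY_TELEMED, overhead, None))
        lines.extend(
            CostLine(day, CATEGORY_TELEMED, fee, pid) for pid in range(n_patients)
        )
    return lines


def admission_total_cost(
    record: AdmissionRecord, ldf: LdfGroup, catalogue, euro_per_point: float
) -> dict:
    """Price one completed admission; returns cents by inpatient category.

    The flat-rate trim logic applies to the total in-hospital days
    (ward + ICU); ICU days are additionally paid through the daily
    supplement.  Fatal stays are priced by the days actually accrued.
    """
    total_days = record.ward_days + record.icu_days
    return {
        CATEGORY_WARD: ldf_reimbursement(total_days, ldf, euro_per_point),
        CATEGORY_ICU: icu_supplement(record.icu_days, ldf, euro_per_point),
        CATEGORY_IMP: imp_cost(record.imp_codes, catalogue, euro_per_point),
    }
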