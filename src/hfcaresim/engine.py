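"""The discrete-event scheduler.

Time advances in whole days over a half-open horizon ``[0, horizon_days)``.
Each day, hospitalised patients count down their stay (discharging with
their drawn NYHA transition, or dying in hospital), and outpatient patients
run their arm's care cycle — daily for conventional care, weekly for
telemonitored care — plus any routine visits scheduled for that day.  New
admissions are resolved on the spot by the inpatient module and priced by
the cost engine.  Telemonitoring system fees accrue at month boundaries
(month = 30.4375 days); per-patient fees stop for dead patients, while the
variant-B cohort overhead runs for the whole horizon (it is a system-level
service contract).

Randomness is organised as one named substream per patient per pathway
(init / routine / outpatient / inpatient), so that enlarging the cohort
never perturbs the trajectories of existing patients under a fixed seed,
and runs are independent given their run index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import costs as co
from . import events as ev
from .config import (
    CONVENTIONAL,
    TELEMEDICAL,
    ConstraintError,
    ScenarioConfig,
    validate_scenario,
)
from .conventional import conventional_daily_cycle, schedule_routine_visits
from .inpatient import run_admission
from .kernels import RngStream, draw_categorical
from .telemedical import is_control_day, telemedical_control_cycle

__all__ = [
    "MONTH_DAYS",
    "PatientState",
    "RunResult",
    "ScenarioResult",
    "step_day",
    "run_single",
    "run_scenario",
    "load_result",
]

MONTH_DAYS = 30.4375  # 365.25 / 12; the model mixes daily steps with monthly fees

OUTPATIENT = "outpatient"
HOSPITALIZED = "hospitalized"
DEAD = "dead"


@dataclass
class PatientState:
    """One simulated patient."""

    id: int
    nyha: int
    status: str = OUTPATIENT
    days_remaining_in_hospital: int = 0
    arm: str = CONVENTIONAL
    pending_admission: Optional[object] = None  # AdmissionRecord while hospitalised


class _RunContext:
    """Per-run bookkeeping: named substreams and pre-drawn routine visits."""

    def __init__(self, cfg: ScenarioConfig, run_index: int):
        self.run_index = run_index
        base = f"{cfg.arm}/run-{run_index}"
        self.outpatient_streams = {}
        self.inpatient_streams = {}
        self.routine_by_day = {}  # pid -> {day: [kinds]}
        self.initial_nyha = {}
        for pid in range(cfg.n_patients):
            plabel = f"{base}/patient-{pid}"
            init = RngStream(cfg.seed, plabel + "/init")
            nyha = 1 + draw_categorical(cfg.nyha_distribution, init)
            self.initial_nyha[pid] = nyha
            self.outpatient_streams[pid] = RngStream(cfg.seed, plabel + "/outpatient")
            self.inpatient_streams[pid] = RngStream(cfg.seed, plabel + "/inpatient")
            routine_rng = RngStream(cfg.seed, plabel + "/routine")
            # Routine visits are scheduled once, at the patient's initial
            # severity class (rates are class-resolved in the config).
            schedule = schedule_routine_visits(
                cfg.nyha_params[nyha], cfg.horizon_days, routine_rng
            )
            by_day: dict = {}
            for day, kind in schedule:
                by_day.setdefault(day, []).append(kind)
            self.routine_by_day[pid] = by_day

    def make_cohort(self, cfg: ScenarioConfig) -> list:
        return [
            PatientState(id=pid, nyha=self.initial_nyha[pid], arm=cfg.arm)
            for pid in range(cfg.n_patients)
        ]


def _admit(patient, cfg, day, ctx, events, lines) -> None:
    params = cfg.nyha_params[patient.nyha]
    rec = run_admission(
        patient,
        params,
        ctx.inpatient_streams[patient.id],
        admit_day=day,
        los_dispersion=cfg.los_dispersion,
    )
    events.append(
        ev.EventRecord(day=day, patient_id=patient.id, kind=ev.WARD_STAY,
                       payload={"days": rec.ward_days})
    )
    if rec.icu_days > 0:
        events.append(
            ev.EventRecord(day=day, patient_id=patient.id, kind=ev.ICU_STAY,
                           payload={"days": rec.icu_days})
        )
    for code in rec.imp_codes:
        events.append(
            ev.EventRecord(day=day, patient_id=patient.id, kind=ev.IMP,
                           payload={"code": code})
        )
    by_cat = co.admission_total_cost(
        rec, cfg.ldf[patient.nyha], cfg.imp_catalogue, cfg.tariffs.euro_per_ldf_point
    )
    for category, amount in by_cat.items():
        if amount:
            lines.append(co.CostLine(day, category, amount, patient.id))
    patient.status = HOSPITALIZED
    patient.days_remaining_in_hospital = rec.total_days
    patient.pending_admission = rec


def step_day(cohort: list, cfg: ScenarioConfig, day: int, ctx: _RunContext):
    """Advance every patient by one day; returns (events, cost_lines)."""
    events: list = []
    lines: list = []
    telemed = cfg.arm == TELEMEDICAL
    control = telemed and is_control_day(day)

    for patient in cohort:
        if patient.status == DEAD:
            continue

        if patient.status == HOSPITALIZED:
            patient.days_remaining_in_hospital -= 1
            if patient.days_remaining_in_hospital == 0:
                rec = patient.pending_admission
                patient.pending_admission = None
                if rec.died_in_hospital:
                    patient.status = DEAD
                    events.append(
                        ev.EventRecord(day=day, patient_id=patient.id,
                                       kind=ev.IN_HOSPITAL_DEATH,
                                       payload={"nyha": rec.nyha_at_admit})
                    )
                else:
                    # Re-enters outpatient circulation the day after discharge.
                    patient.status = OUTPATIENT
                    patient.nyha = rec.nyha_at_discharge
                    events.append(
                        ev.EventRecord(day=day, patient_id=patient.id,
                                       kind=ev.DISCHARGE)
                    )
            continue

        # Outpatient: routine visits first, then the arm's care cycle.
        for kind in ctx.routine_by_day[patient.id].get(day, ()):
            events.append(ev.EventRecord(day=day, patient_id=patient.id, kind=kind))
            amount = co.outpatient_event_cost(kind, cfg.tariffs, cfg.toggles)
            if amount:
                lines.append(co.CostLine(day, co.CATEGORY_OUTPATIENT, amount, patient.id))

        params = cfg.nyha_params[patient.nyha]
        rng = ctx.outpatient_streams[patient.id]
        if telemed:
            if not control:
                continue
            outcome = telemedical_control_cycle(patient, params, cfg.toggles, rng, day=day)
        else:
            outcome = conventional_daily_cycle(patient, params, cfg.toggles, rng, day=day)

        if outcome.kind == ev.NONE:
            continue
        payload = {"nyha": patient.nyha} if outcome.kind == ev.EXTRAMURAL_DEATH else None
        events.append(
            ev.EventRecord(day=day, patient_id=patient.id, kind=outcome.kind,
                           payload=payload)
        )
        amount = co.outpatient_event_cost(outcome.kind, cfg.tariffs, cfg.toggles)
        if amount:
            lines.append(co.CostLine(day, co.CATEGORY_OUTPATIENT, amount, patient.id))
        if outcome.kind == ev.EXTRAMURAL_DEATH:
            patient.status = DEAD
        elif outcome.kind in ev.ADMISSION_KINDS:
            _admit(patient, cfg, day, ctx, events, lines)

    if telemed:
        lines.extend(_telemed_fees(cohort, cfg, day))
    return events, lines


def _telemed_fees(cohort, cfg: ScenarioConfig, day: int) -> list:
    fin = cfg.financing
    lines: list = []
    if day == 0 and fin.variant == "B":
        acq = co.cents(fin.acquisition_per_system_eur)
        if acq:
            lines.extend(
                co.CostLine(0, co.CATEGORY_TELEMED, acq, p.id) for p in cohort
            )
    month_completed = int((day + 1) // MONTH_DAYS) > int(day // MONTH_DAYS)
    if not month_completed:
        return lines
    if fin.variant == "A":
        rate = co.cents(fin.monthly_rate_per_patient_eur)
        if rate:
            lines.extend(
                co.CostLine(day, co.CATEGORY_TELEMED, rate, p.id)
                for p in cohort
                if p.status != DEAD
            )
    else:
        overhead = co.cents(fin.monthly_overhead_eur)
        if overhead:
            lines.append(co.CostLine(day, co.CATEGORY_TELEMED, overhead, None))
        fee = co.cents(fin.physician_fee_per_patient_month_eur)
        if fee:
            lines.extend(
                co.CostLine(day, co.CATEGORY_TELEMED, fee, p.id)
                for p in cohort
                if p.status != DEAD
            )
    return lines


@dataclass
class RunResult:
    """One simulation run: daily series, event log and booked cost lines."""

    run_index: int
    seed: int
    horizon_days: int
    n_patients: int
    cum_cost_cents: dict  # category -> int64 array over days
    alive: np.ndarray
    dead: np.ndarray
    nyha_counts: np.ndarray  # shape (4, horizon)
    events: list
    cost_lines: list

    @property
    def cum_total_cents(self) -> np.ndarray:
        return sum(self.cum_cost_cents[c] for c in co.CATEGORIES)

    @property
    def total_cost_cents(self) -> int:
        return int(self.cum_total_cents[-1]) if self.horizon_days else 0

    @property
    def deaths(self) -> int:
        return int(self.dead[-1]) if self.horizon_days else 0


@dataclass
class ScenarioResult:
    """All runs of one scenario plus across-run mean/std daily series (euros)."""

    config: ScenarioConfig
    runs: list
    mean_cum_total_eur: np.ndarray
    std_cum_total_eur: np.ndarray
    mean_cum_by_cat_eur: dict
    mean_alive: np.ndarray
    mean_dead: np.ndarray
    mean_nyha: np.ndarray  # shape (4, horizon)

    @property
    def name(self) -> str:
        return self.config.name

    @property
    def arm(self) -> str:
        return self.config.arm

    @property
    def horizon_days(self) -> int:
        return self.config.horizon_days

    @property
    def n_patients(self) -> int:
        return self.config.n_patients

    @property
    def deaths_per_run(self) -> list:
        return [r.deaths for r in self.runs]

    @property
    def deaths_mean(self) -> float:
        return float(np.mean(self.deaths_per_run))

    def summary(self) -> dict:
        """Flat summary of headline outputs (used by reports and sweeps)."""
        out = {
            "name": self.name,
            "arm": self.arm,
            "n_patients": self.n_patients,
            "horizon_days": self.horizon_days,
            "n_runs": len(self.runs),
            "seed": self.config.seed,
            "total_cost_eur": float(self.mean_cum_total_eur[-1]) if self.horizon_days else 0.0,
            "deaths": self.deaths_mean,
            "deaths_per_run": self.deaths_per_run,
        }
        for cat in co.CATEGORIES:
            series = self.mean_cum_by_cat_eur[cat]
            out[f"cost_{cat}_eur"] = float(series[-1]) if self.horizon_days else 0.0
        return out

    # -- serialisation ------------------------------------------------------

    def save(self, directory) -> Path:
        """Write summary JSON, mean daily series and per-run logs as CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)
        frame = {"day": np.arange(self.horizon_days)}
        frame["cum_total_eur"] = self.mean_cum_total_eur
        frame["cum_total_std_eur"] = self.std_cum_total_eur
        for cat in co.CATEGORIES:
            frame[f"cum_{cat}_eur"] = self.mean_cum_by_cat_eur[cat]
        frame["alive"] = self.mean_alive
        frame["dead"] = self.mean_dead
        for k in range(4):
            frame[f"nyha{k + 1}"] = self.mean_nyha[k]
        pd.DataFrame(frame).to_csv(directory / "mean_daily.csv", index=False)
        for run in self.runs:
            pd.DataFrame(
                [
                    {
                        "day": e.day,
                        "patient_id": e.patient_id,
                        "kind": e.kind,
                        "payload": json.dumps(e.payload) if e.payload else "",
                    }
                    for e in run.events
                ]
            ).to_csv(directory / f"run_{run.run_index}_events.csv", index=False)
            pd.DataFrame(
                [
                    {
                        "day": l.day,
                        "patient_id": "" if l.patient_id is None else l.patient_id,
                        "category": l.category,
                        "amount_eur": co.eur(l.amount_cents),
                    }
                    for l in run.cost_lines
                ]
            ).to_csv(directory / f"run_{run.run_index}_costlines.csv", index=False)
        return directory


class LoadedResult:
    """A :class:`ScenarioResult` view re-read from a result directory.

    Carries exactly what the reporting layer needs (summary and mean daily
    series), so comparisons can be made long after the runs finished.
    """

    def __init__(self, directory):
        directory = Path(directory)
        with open(directory / "summary.json", "r", encoding="utf-8") as fh:
            self._summary = json.load(fh)
        daily = pd.read_csv(directory / "mean_daily.csv")
        self.mean_cum_total_eur = daily["cum_total_eur"].to_numpy()
        self.mean_cum_by_cat_eur = {
            cat: daily[f"cum_{cat}_eur"].to_numpy() for cat in co.CATEGORIES
        }
        self.mean_alive = daily["alive"].to_numpy()
        self.mean_dead = daily["dead"].to_numpy()
        self.mean_nyha = np.vstack([daily[f"nyha{k + 1}"].to_numpy() for k in range(4)])

    @property
    def name(self) -> str:
        return self._summary["name"]

    @property
    def arm(self) -> str:
        return self._summary["arm"]

    @property
    def horizon_days(self) -> int:
        return int(self._summary["horizon_days"])

    @property
    def n_patients(self) -> int:
        return int(self._summary["n_patients"])

    @property
    def deaths_per_run(self) -> list:
        return self._summary["deaths_per_run"]

    @property
    def deaths_mean(self) -> float:
        return float(self._summary["deaths"])

    def summary(self) -> dict:
        return dict(self._summary)


def load_result(directory) -> LoadedResult:
    return LoadedResult(directory)


def run_single(cfg: ScenarioConfig, run_index: int = 0) -> RunResult:
    """Execute one complete run; fully determined by (config, seed, run_index)."""
    violations = validate_scenario(cfg)
    if violations:
        raise ConstraintError(violations)

    ctx = _RunContext(cfg, run_index)
    cohort = ctx.make_cohort(cfg)
    horizon = cfg.horizon_days

    daily_cost = {cat: np.zeros(horizon, dtype=np.int64) for cat in co.CATEGORIES}
    alive = np.zeros(horizon, dtype=np.int64)
    dead = np.zeros(horizon, dtype=np.int64)
    nyha_counts = np.zeros((4, horizon), dtype=np.int64)
    all_events: list = []
    all_lines: list = []

    for day in range(horizon):
        events, lines = step_day(cohort, cfg, day, ctx)
        all_events.extend(events)
        all_lines.extend(lines)
        for line in lines:
            daily_cost[line.category][day] += line.amount_cents
        n_dead = sum(1 for p in cohort if p.status == DEAD)
        dead[day] = n_dead
        alive[day] = cfg.n_patients - n_dead
        for p in cohort:
            if p.status != DEAD:
                nyha_counts[p.nyha - 1, day] += 1

    return RunResult(
        run_index=run_index,
        seed=cfg.seed,
        horizon_days=horizon,
        n_patients=cfg.n_patients,
        cum_cost_cents={cat: np.cumsum(daily_cost[cat]) for cat in co.CATEGORIES},
        alive=alive,
        dead=dead,
        nyha_counts=nyha_counts,
        events=all_events,
        cost_lines=all_lines,
    )


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Execute ``cfg.n_runs`` independent runs and average the daily series."""
    runs = [run_single(cfg, k) for k in range(cfg.n_runs)]
    totals = np.vstack([r.cum_total_cents for r in runs]).astype(float) / 100.0
    by_cat = {
        cat: np.vstack([r.cum_cost_cents[cat] for r in runs]).astype(float) / 100.0
        for cat in co.CATEGORIES
    }
    return ScenarioResult(
        config=cfg,
        runs=runs,
        mean_cum_total_eur=totals.mean(axis=0),
        std_cum_total_eur=totals.std(axis=0),
        mean_cum_by_cat_eur={cat: by_cat[cat].mean(axis=0) for cat in co.CATEGORIES},
        mean_alive=np.vstack([r.alive for r in runs]).mean(axis=0),
        mean_dead=np.vstack([r.dead for r in runs]).mean(axis=0),
        mean_nyha=np.stack([r.nyha_counts for r in runs]).mean(axis=0),
    )
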