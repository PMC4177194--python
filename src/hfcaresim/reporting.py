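"""Reports over scenario results.

Turns simulated scenarios into the comparisons a payer-side analyst wants:
yearly cost totals with the telemedical arm expressed as a percentage of
conventional care (conventional = 100%), break-even detection on the mean
cumulative cost curves, mortality counts by cause and severity class, the
NYHA distribution over time, and one-at-a-time sensitivity sweeps.

Every number here is recomputed from the daily series and event logs of the
results — reports carry no state of their own, so anything printed can be
re-derived from a serialised result directory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import costs as co
from . import events as ev
from .config import ScenarioConfig
from .engine import ScenarioResult, run_scenario

__all__ = [
    "YEAR_SLICE_DAYS",
    "ComparisonReport",
    "compare_arms",
    "break_even",
    "mortality_summary",
    "nyha_timeseries",
    "sensitivity_sweep",
]

YEAR_SLICE_DAYS = 365  # reporting slices: days [0,365), [365,730), [730,1095)


def break_even(series_a, series_b) -> Optional[int]:
    """First day ``d >= 1`` at which ``series_b(d) <= series_a(d)``.

    Intended for cumulative cost curves where arm B starts out more
    expensive (``series_b(0) > series_a(0)``); returns ``None`` if the
    curves never cross within the horizon.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    crossed = np.nonzero(b[1:] <= a[1:])[0]
    if crossed.size == 0:
        return None
    return int(crossed[0]) + 1


@dataclass
class ComparisonReport:
    """Two-arm cost and mortality comparison on a common horizon."""

    arm_a: str
    arm_b: str
    horizon_days: int
    n_patients: int
    years: list  # per reporting-year slice: totals and percent-of-A
    cumulative_pct: list  # percent-of-A on cumulative costs at year ends
    break_even_day: Optional[int]
    deaths: dict  # arm label -> mean deaths
    category_totals_eur: dict  # arm label -> {category: total}

    def to_dict(self) -> dict:
        return {
            "arm_a": self.arm_a,
            "arm_b": self.arm_b,
            "horizon_days": self.horizon_days,
            "n_patients": self.n_patients,
            "years": self.years,
            "cumulative_pct": self.cumulative_pct,
            "break_even_day": self.break_even_day,
            "deaths": self.deaths,
            "category_totals_eur": self.category_totals_eur,
        }

    def normalized_bar_frame(self) -> pd.DataFrame:
        """Bar-chart data: per year, arm A fixed at 100%, arm B relative."""
        rows = []
        for y in self.years:
            rows.append(
                {
                    "year": y["year"],
                    self.arm_a + "_pct": 100.0,
                    self.arm_b + "_pct": y["pct_of_a"],
                }
            )
        return pd.DataFrame(rows)


def _year_slices(horizon_days: int) -> list:
    slices = []
    start = 0
    year = 1
    while start < horizon_days:
        end = min(start + YEAR_SLICE_DAYS, horizon_days)
        slices.append((year, start, end))
        start = end
        year += 1
    return slices


def _slice_total(cum: np.ndarray, start: int, end: int) -> float:
    before = float(cum[start - 1]) if start > 0 else 0.0
    return float(cum[end - 1]) - before


def _pct(b: float, a: float) -> float:
    if a == 0.0:
        return 100.0 if b == 0.0 else float("inf")
    return 100.0 * b / a


def compare_arms(result_a, result_b) -> ComparisonReport:
    """Compare two scenario results (A is the reference, typically
    conventional care = 100%)."""
    if result_a.horizon_days != result_b.horizon_days:
        raise ValueError("results cover different horizons")
    if result_a.n_patients != result_b.n_patients:
        raise ValueError("results cover different cohort sizes")

    cum_a = result_a.mean_cum_total_eur
    cum_b = result_b.mean_cum_total_eur
    years = []
    cumulative_pct = []
    for year, start, end in _year_slices(result_a.horizon_days):
        total_a = _slice_total(cum_a, start, end)
        total_b = _slice_total(cum_b, start, end)
        years.append(
            {
                "year": year,
                "start_day": start,
                "end_day": end,
                "total_a_eur": total_a,
                "total_b_eur": total_b,
                "pct_of_a": _pct(total_b, total_a),
            }
        )
        cumulative_pct.append(
            {
                "year": year,
                "end_day": end,
                "pct_of_a": _pct(float(cum_b[end - 1]), float(cum_a[end - 1])),
            }
        )

    label_a = getattr(result_a, "name", "arm_a")
    label_b = getattr(result_b, "name", "arm_b")
    # A break-even day is only meaningful when arm B starts out the more
    # expensive one and its cumulative curve later falls to arm A's.
    be = break_even(cum_a, cum_b) if cum_b[0] > cum_a[0] else None
    return ComparisonReport(
        arm_a=label_a,
        arm_b=label_b,
        horizon_days=result_a.horizon_days,
        n_patients=result_a.n_patients,
        years=years,
        cumulative_pct=cumulative_pct,
        break_even_day=be,
        deaths={label_a: result_a.deaths_mean, label_b: result_b.deaths_mean},
        category_totals_eur={
            label_a: {
                cat: float(result_a.mean_cum_by_cat_eur[cat][-1])
                for cat in co.CATEGORIES
            },
            label_b: {
                cat: float(result_b.mean_cum_by_cat_eur[cat][-1])
                for cat in co.CATEGORIES
            },
        },
    )


def mortality_summary(result: ScenarioResult) -> dict:
    """Deaths by cause and NYHA class, averaged across runs.

    Counts come from the event log and are cross-checked against the daily
    dead-count series of every run.
    """
    per_run = []
    for run in result.runs:
        in_hospital = 0
        extramural = 0
        by_class = {k: 0 for k in (1, 2, 3, 4)}
        for e in run.events:
            if e.kind == ev.IN_HOSPITAL_DEATH:
                in_hospital += 1
            elif e.kind == ev.EXTRAMURAL_DEATH:
                extramural += 1
            else:
                continue
            if e.payload and "nyha" in e.payload:
                by_class[e.payload["nyha"]] += 1
        total = in_hospital + extramural
        if run.horizon_days and total != run.deaths:
            raise AssertionError(
                f"event log deaths ({total}) disagree with daily series ({run.deaths})"
            )
        per_run.append(
            {"in_hospital": in_hospital, "extramural": extramural,
             "total": total, "by_class": by_class}
        )
    n = len(per_run)
    return {
        "total_mean": sum(r["total"] for r in per_run) / n,
        "in_hospital_mean": sum(r["in_hospital"] for r in per_run) / n,
        "extramural_mean": sum(r["extramural"] for r in per_run) / n,
        "by_class_mean": {
            k: sum(r["by_class"][k] for r in per_run) / n for k in (1, 2, 3, 4)
        },
        "per_run": per_run,
    }


def nyha_timeseries(result) -> pd.DataFrame:
    """Mean daily patient counts per NYHA class (columns nyha1..nyha4)."""
    data = {f"nyha{k + 1}": result.mean_nyha[k] for k in range(4)}
    frame = pd.DataFrame(data)
    frame.insert(0, "day", np.arange(len(frame)))
    return frame


def _resolve_parent(cfg, path: str):
    tokens = path.split(".")
    parents = [cfg]
    for token in tokens[:-1]:
        next_level = []
        for obj in parents:
            if isinstance(obj, dict):
                if token == "*":
                    next_level.extend(obj.values())
                    continue
                key = int(token) if token.lstrip("-").isdigit() else token
                if key not in obj:
                    raise KeyError(f"key {token!r} not found while resolving {path!r}")
                next_level.append(obj[key])
            else:
                if not hasattr(obj, token):
                    raise KeyError(f"attribute {token!r} not found while resolving {path!r}")
                next_level.append(getattr(obj, token))
        parents = next_level
    return parents, tokens[-1]


def _set_path(cfg, path: str, value) -> None:
    parents, leaf = _resolve_parent(cfg, path)
    for obj in parents:
        if isinstance(obj, dict):
            key = int(leaf) if leaf.lstrip("-").isdigit() else leaf
            if key not in obj:
                raise KeyError(f"key {leaf!r} not found while resolving {path!r}")
            obj[key] = value
        else:
            if not hasattr(obj, leaf):
                raise KeyError(f"attribute {leaf!r} not found while resolving {path!r}")
            setattr(obj, leaf, value)


def sensitivity_sweep(
    base: ScenarioConfig,
    parameter_path: str,
    values: Sequence,
    outputs: Sequence[str] = ("total_cost_eur", "deaths"),
) -> pd.DataFrame:
    """One-at-a-time sensitivity analysis.

    Runs one full scenario per value of ``parameter_path`` (dot-separated;
    dict levels take integer keys and ``*`` fans out over all entries, e.g.
    ``"nyha_params.*.in_hospital_mortality_prob"``), holding everything else
    — including the seed — fixed, and tabulates the requested summary
    outputs.
    """
    rows = []
    for value in values:
        cfg = copy.deepcopy(base)
        _set_path(cfg, parameter_path, value)
        summary = run_scenario(cfg).summary()
        row = {"value": value}
        for key in outputs:
            if key not in summary:
                raise KeyError(f"unknown report output {key!r}")
            row[key] = summary[key]
        rows.append(row)
    return pd.DataFrame(rows)
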