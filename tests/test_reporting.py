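"""Reporting: break-even detection, arm comparison, mortality, sweeps, CLI."""

from types import SimpleNamespace

import numpy as np
import pytest
from click.testing import CliRunner

from hfcaresim.cli import main as cli_main
from hfcaresim.config import load_scenario, write_scenario
from hfcaresim.costs import CATEGORIES
from hfcaresim.engine import run_scenario
from hfcaresim.reporting import (
    break_even,
    compare_arms,
    mortality_summary,
    nyha_timeseries,
    sensitivity_sweep,
)

from conftest import make_config


def brute_force_break_even(a, b):
    """Linear-scan oracle for the first day d >= 1 with b[d] <= a[d]."""
    for d in range(1, len(a)):
        if b[d] <= a[d]:
            return d
    return None


def fake_result(cum_total, name="fake", n_patients=100, deaths=0.0):
    horizon = len(cum_total)
    return SimpleNamespace(
        name=name,
        horizon_days=horizon,
        n_patients=n_patients,
        mean_cum_total_eur=np.asarray(cum_total, dtype=float),
        mean_cum_by_cat_eur={
            cat: np.zeros(horizon) if cat != "ward" else np.asarray(cum_total, float)
            for cat in CATEGORIES
        },
        deaths_mean=deaths,
    )


class TestBreakEven:
    def test_never_crossing_curves(self):
        t = np.arange(100, dtype=float)
        assert break_even(t, t + 5.0) is None

    def test_constructed_crossing_at_two_years(self):
        t = np.arange(1095, dtype=float)
        a = 2.0 * t
        b = t + 730.0
        assert break_even(a, b) == 730

    def test_equal_series_cross_on_day_one(self):
        t = np.arange(50, dtype=float)
        assert break_even(t, t.copy()) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            break_even(np.zeros(5), np.zeros(6))

    def test_matches_the_brute_force_oracle_on_random_monotone_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(2, 200))
            a = np.cumsum(rng.random(n))
            b = np.cumsum(rng.random(n)) + rng.uniform(-2, 2)
            assert break_even(a, b) == brute_force_break_even(a, b)


class TestCompareArms:
    def test_identical_results_give_100_percent_everywhere(self):
        t = np.cumsum(np.full(730, 3.0))
        report = compare_arms(fake_result(t, "a"), fake_result(t, "b"))
        assert [y["pct_of_a"] for y in report.years] == [100.0, 100.0]
        assert report.deaths == {"a": 0.0, "b": 0.0}

    def test_twenty_percent_excess_in_year_one(self):
        t = np.cumsum(np.full(365, 10.0))
        report = compare_arms(fake_result(t), fake_result(1.2 * t, "b"))
        assert report.years[0]["pct_of_a"] == pytest.approx(120.0)

    def test_break_even_detected_from_mean_curves(self):
        t = np.arange(1095, dtype=float)
        report = compare_arms(fake_result(2.0 * t), fake_result(t + 100.0, "b"))
        assert report.break_even_day == 100

    def test_swapping_arms_inverts_each_yearly_percentage(self):
        rng = np.random.default_rng(5)
        a = np.cumsum(rng.random(800) + 0.1)
        b = np.cumsum(rng.random(800) + 0.1)
        forward = compare_arms(fake_result(a), fake_result(b, "b"))
        backward = compare_arms(fake_result(b, "b"), fake_result(a))
        for fy, by in zip(forward.years, backward.years):
            assert fy["pct_of_a"] * by["pct_of_a"] == pytest.approx(100.0**2)

    def test_mismatched_horizons_rejected(self):
        with pytest.raises(ValueError):
            compare_arms(fake_result(np.zeros(10)), fake_result(np.zeros(11)))


class TestMortalitySummary:
    def test_inert_scenario_has_no_deaths(self):
        summary = mortality_summary(run_scenario(make_config(n_runs=2)))
        assert summary["total_mean"] == 0.0
        assert summary["by_class_mean"] == {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_forced_death_is_counted_in_hospital_with_its_class(self):
        cfg = make_config(
            params=dict(
                worsening_prob_per_day=1.0,
                emergency_prob_given_worsening=1.0,
                in_hospital_mortality_prob=1.0,
            ),
            n_patients=1,
            nyha_distribution=(0.0, 0.0, 1.0, 0.0),
            horizon_days=30,
        )
        summary = mortality_summary(run_scenario(cfg))
        assert summary["in_hospital_mean"] == 1.0
        assert summary["extramural_mean"] == 0.0
        assert summary["by_class_mean"][3] == 1.0


class TestNyhaTimeseries:
    def test_counts_sum_to_the_alive_series(self):
        cfg = make_config(
            params=dict(
                worsening_prob_per_day=0.05,
                emergency_prob_given_worsening=1.0,
                in_hospital_mortality_prob=0.3,
                discharge_transition_probs=(0.3, 0.4, 0.3),
            ),
            n_patients=20,
            horizon_days=100,
            n_runs=2,
        )
        result = run_scenario(cfg)
        frame = nyha_timeseries(result)
        sums = frame[["nyha1", "nyha2", "nyha3", "nyha4"]].sum(axis=1).to_numpy()
        assert np.allclose(sums, result.mean_alive)


class TestSensitivitySweep:
    def test_zero_monthly_rate_zeroes_the_system_subtotal(self):
        cfg = make_config(arm="telemedical", horizon_days=70)
        table = sensitivity_sweep(
            cfg, "financing.monthly_rate_per_patient_eur", [0.0],
            outputs=("cost_telemed_system_eur",),
        )
        assert table["cost_telemed_system_eur"].tolist() == [0.0]

    def test_mortality_extremes(self):
        cfg = make_config(
            params=dict(
                worsening_prob_per_day=1.0, emergency_prob_given_worsening=1.0
            ),
            n_patients=3,
            horizon_days=30,
        )
        table = sensitivity_sweep(
            cfg, "nyha_params.*.in_hospital_mortality_prob", [0.0, 1.0],
            outputs=("deaths",),
        )
        assert table["deaths"].tolist() == [0.0, 3.0]

    def test_cohort_size_scales_system_cost_linearly(self):
        cfg = make_config(arm="telemedical", horizon_days=70)
        table = sensitivity_sweep(
            cfg, "n_patients", [2, 4, 8], outputs=("total_cost_eur",)
        )
        totals = table["total_cost_eur"].to_numpy()
        assert np.allclose(totals, totals[0] * np.array([1, 2, 4]))

    def test_unresolvable_path_rejected(self):
        with pytest.raises(KeyError):
            sensitivity_sweep(make_config(), "no.such.path", [1.0])


class TestCli:
    def test_fixtures_subcommand_writes_three_scenarios(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fixtures", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        files = sorted(p.name for p in tmp_path.glob("*.yaml"))
        assert files == [
            "study_scenario_conventional.yaml",
            "study_scenario_tm_a.yaml",
            "study_scenario_tm_b.yaml",
        ]
        load_scenario(tmp_path / files[0])  # written files are valid scenarios

    def test_run_and_compare_round_trip(self, tmp_path):
        runner = CliRunner()
        conv = make_config(
            params=dict(worsening_prob_per_day=0.05,
                        emergency_prob_given_worsening=1.0),
            n_patients=5, horizon_days=80, n_runs=2, name="mini_conv",
        )
        tm = make_config(
            arm="telemedical",
            params=dict(tm_alarm_prob_per_cycle=0.3,
                        emergency_prob_given_worsening=1.0),
            n_patients=5, horizon_days=80, n_runs=2, name="mini_tm",
        )
        for cfg in (conv, tm):
            write_scenario(cfg, tmp_path / f"{cfg.name}.yaml")
            result = runner.invoke(cli_main, [
                "run", str(tmp_path / f"{cfg.name}.yaml"),
                "--out", str(tmp_path / cfg.name), "-v",
            ])
            assert result.exit_code == 0, result.output
            assert (tmp_path / cfg.name / "summary.json").exists()
        result = runner.invoke(cli_main, [
            "compare", str(tmp_path / "mini_conv"), str(tmp_path / "mini_tm"),
            "--out", str(tmp_path / "cmp"),
        ])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cmp" / "comparison.json").exists()
        assert (tmp_path / "cmp" / "normalized_costs.csv").exists()

    def test_bad_arguments_exit_nonzero(self):
        runner = CliRunner()
        assert runner.invoke(cli_main, ["run", "/no/such/file.yaml"]).exit_code != 0
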