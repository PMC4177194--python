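"""Outpatient pathways: conventional daily cycle, telemedical weekly cycle,
routine visit scheduling."""

import itertools
import math

import pytest

from hfcaresim import events as ev
from hfcaresim.config import Toggles
from hfcaresim.conventional import (
    DAYS_PER_YEAR,
    conventional_daily_cycle,
    schedule_routine_visits,
)
from hfcaresim.events import StateError
from hfcaresim.kernels import RngStream
from hfcaresim.telemedical import (
    is_control_day,
    telemedical_control_cycle,
)

from conftest import make_params, make_patient


def three_sigma(p, n):
    return 3.0 * math.sqrt(p * (1 - p) / n)


def conventional_outcome_distribution(p, extramural_on: bool) -> dict:
    """Hand-enumerated decision-tree probabilities for the conventional cycle.

    Independent oracle for the branch structure: worsening -> emergency |
    (contact -> improvement | death | referral | carry-over).
    """
    w = p.worsening_prob_per_day
    e = p.emergency_prob_given_worsening
    contacts = dict(
        zip(
            (ev.MEDICATION_CHANGE, ev.GP_VISIT, ev.SPECIALIST_VISIT, ev.AMBULANCE_VISIT),
            (p.medication_change_prob, *p.provider_choice_probs),
        )
    )
    i = p.improvement_prob_after_contact
    m = p.extramural_mortality_prob if extramural_on else 0.0
    r = p.hospitalization_prob_no_improvement
    dist = {ev.NONE: 1.0 - w, ev.EMERGENCY_ADMISSION: w * e}
    dist[ev.EXTRAMURAL_DEATH] = w * (1 - e) * (1 - i) * m
    dist[ev.REFERRAL_ADMISSION] = w * (1 - e) * (1 - i) * (1 - m) * r
    for kind, pc in contacts.items():
        # a contact is reported on improvement or on a failed cycle that
        # neither killed nor referred the patient
        dist[kind] = w * (1 - e) * pc * (i + (1 - i) * (1 - m) * (1 - r))
    return dist


class TestConventionalDailyCycle:
    def test_no_worsening_means_no_event(self):
        params = make_params(worsening_prob_per_day=0.0)
        rng = RngStream(0, "conv")
        for day in range(100):
            assert conventional_daily_cycle(
                make_patient(), params, Toggles(), rng, day=day
            ).kind == ev.NONE

    def test_certain_emergency_chain(self):
        params = make_params(
            worsening_prob_per_day=1.0, emergency_prob_given_worsening=1.0
        )
        rng = RngStream(1, "conv")
        assert all(
            conventional_daily_cycle(make_patient(), params, Toggles(), rng).kind
            == ev.EMERGENCY_ADMISSION
            for _ in range(100)
        )

    def test_forced_gp_path(self):
        params = make_params(
            worsening_prob_per_day=1.0,
            emergency_prob_given_worsening=0.0,
            medication_change_prob=0.0,
            provider_choice_probs=(1.0, 0.0, 0.0),
            improvement_prob_after_contact=1.0,
        )
        rng = RngStream(2, "conv")
        assert all(
            conventional_daily_cycle(make_patient(), params, Toggles(), rng).kind
            == ev.GP_VISIT
            for _ in range(1000)
        )

    def test_outcome_distribution_matches_the_decision_tree_oracle(self):
        n = 50_000
        params = make_params(
            worsening_prob_per_day=0.4,
            emergency_prob_given_worsening=0.3,
            medication_change_prob=0.3,
            provider_choice_probs=(0.4, 0.2, 0.1),
            improvement_prob_after_contact=0.7,
            extramural_mortality_prob=0.1,
            hospitalization_prob_no_improvement=0.6,
        )
        toggles = Toggles(extramural_mortality=True)
        expected = conventional_outcome_distribution(params, extramural_on=True)
        assert sum(expected.values()) == pytest.approx(1.0, abs=1e-12)
        rng = RngStream(33, "conv-tree")
        counts: dict = {}
        for _ in range(n):
            kind = conventional_daily_cycle(make_patient(), params, toggles, rng).kind
            counts[kind] = counts.get(kind, 0) + 1
        for kind, p_expected in expected.items():
            freq = counts.get(kind, 0) / n
            assert freq == pytest.approx(p_expected, abs=three_sigma(p_expected, n)), kind

    def test_extramural_death_never_occurs_when_toggled_off(self):
        params = make_params(
            worsening_prob_per_day=1.0,
            emergency_prob_given_worsening=0.0,
            improvement_prob_after_contact=0.0,
            extramural_mortality_prob=1.0,
            hospitalization_prob_no_improvement=0.0,
        )
        rng = RngStream(4, "conv")
        kinds = {
            conventional_daily_cycle(make_patient(), params, Toggles(), rng).kind
            for _ in range(500)
        }
        assert ev.EXTRAMURAL_DEATH not in kinds

    def test_hospitalized_or_dead_patients_rejected(self):
        for status in ("hospitalized", "dead"):
            with pytest.raises(StateError):
                conventional_daily_cycle(
                    make_patient(status=status), make_params(), Toggles(), RngStream(0)
                )


class TestRoutineVisits:
    def test_zero_rates_give_no_visits(self):
        assert schedule_routine_visits(make_params(), 365, RngStream(0, "visits")) == []

    @pytest.mark.parametrize(
        "gp_rate,spec_rate",
        [(1.42, 0.3), (2.84, 0.46)],  # conventional and telemedical arm rates
    )
    def test_poisson_rate_recovery(self, gp_rate, spec_rate):
        n_patients, horizon = 1000, 365
        params = make_params(
            gp_visits_per_year=gp_rate, specialist_visits_per_year=spec_rate
        )
        rng = RngStream(7, f"visits-{gp_rate}")
        gp = spec = 0
        for _ in range(n_patients):
            for _, kind in schedule_routine_visits(params, horizon, rng):
                if kind == ev.GP_VISIT:
                    gp += 1
                else:
                    spec += 1
        years = n_patients * horizon / DAYS_PER_YEAR
        assert gp / years == pytest.approx(gp_rate, abs=3 * math.sqrt(gp_rate / years))
        assert spec / years == pytest.approx(
            spec_rate, abs=3 * math.sqrt(spec_rate / years)
        )

    def test_visit_days_lie_within_the_horizon(self):
        params = make_params(gp_visits_per_year=12.0)
        visits = schedule_routine_visits(params, 100, RngStream(8, "visits"))
        assert all(0 <= day < 100 for day, _ in visits)
        assert [d for d, _ in visits] == sorted(d for d, _ in visits)


class TestTelemedicalControlCycle:
    def test_exactly_one_cycle_per_week(self):
        for horizon in (1, 6, 7, 13, 14, 365, 1095):
            assert sum(is_control_day(d) for d in range(horizon)) == horizon // 7

    def test_no_alarm_means_no_event(self):
        params = make_params(tm_alarm_prob_per_cycle=0.0)
        rng = RngStream(0, "tm")
        assert telemedical_control_cycle(
            make_patient(), params, Toggles(), rng, day=6
        ).kind == ev.NONE

    def test_certain_intervention_chain(self):
        params = make_params(
            tm_alarm_prob_per_cycle=1.0,
            emergency_prob_given_worsening=0.0,
            tm_intervention_success_prob=1.0,
        )
        rng = RngStream(1, "tm")
        assert all(
            telemedical_control_cycle(make_patient(), params, Toggles(), rng, day=6).kind
            == ev.INTERVENTION
            for _ in range(200)
        )

    def test_contact_split_with_certain_adaptation(self):
        n = 100_000
        params = make_params(
            tm_alarm_prob_per_cycle=1.0,
            emergency_prob_given_worsening=0.0,
            tm_intervention_success_prob=0.0,
            tm_contact_choice_probs=(0.5, 0.5, 0.0),
            tm_facetoface_adaptation_prob=1.0,
        )
        rng = RngStream(5, "tm-split")
        counts: dict = {}
        for _ in range(n):
            kind = telemedical_control_cycle(
                make_patient(), params, Toggles(), rng, day=6
            ).kind
            counts[kind] = counts.get(kind, 0) + 1
        assert set(counts) == {ev.HOME_VISIT, ev.DOCTOR_VISIT}
        assert counts[ev.HOME_VISIT] / n == pytest.approx(0.5, abs=three_sigma(0.5, n))

    def test_direct_hospitalization_contact_choice(self):
        params = make_params(
            tm_alarm_prob_per_cycle=1.0,
            emergency_prob_given_worsening=0.0,
            tm_intervention_success_prob=0.0,
            tm_contact_choice_probs=(0.0, 0.0, 1.0),
        )
        rng = RngStream(6, "tm")
        assert telemedical_control_cycle(
            make_patient(), params, Toggles(), rng, day=6
        ).kind == ev.REFERRAL_ADMISSION

    def test_severity_transition_applies_after_alarm_cycles(self):
        params = make_params(
            tm_alarm_prob_per_cycle=1.0,
            emergency_prob_given_worsening=0.0,
            tm_intervention_success_prob=1.0,
            discharge_transition_probs=(1.0, 0.0, 0.0),
        )
        patient = make_patient(nyha=3)
        telemedical_control_cycle(patient, params, Toggles(), RngStream(7, "tm"), day=6)
        assert patient.nyha == 2

    def test_off_cycle_day_rejected(self):
        with pytest.raises(StateError):
            telemedical_control_cycle(
                make_patient(), make_params(), Toggles(), RngStream(0), day=3
            )

    def test_hospitalized_patient_rejected(self):
        with pytest.raises(StateError):
            telemedical_control_cycle(
                make_patient(status="hospitalized"), make_params(), Toggles(),
                RngStream(0), day=6,
            )
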