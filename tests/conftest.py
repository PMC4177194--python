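"""Shared fixtures: parameter/scenario factories and the packaged scenarios."""

import pytest

from hfcaresim.config import (
    CostTariffs,
    ImpCatalogueEntry,
    LdfGroup,
    NyhaParameters,
    ScenarioConfig,
    TelemedFinancing,
    Toggles,
    study_default_scenarios,
)
from hfcaresim.engine import PatientState


def make_params(**overrides) -> NyhaParameters:
    """A fully inert parameter set (no events) to force paths from."""
    base = dict(
        worsening_prob_per_day=0.0,
        emergency_prob_given_worsening=0.0,
        medication_change_prob=0.0,
        provider_choice_probs=(1.0, 0.0, 0.0),
        improvement_prob_after_contact=1.0,
        hospitalization_prob_no_improvement=0.0,
        extramural_mortality_prob=0.0,
        period_hospitalization_prob=0.0,
        gp_visits_per_year=0.0,
        specialist_visits_per_year=0.0,
        icu_admission_prob=0.0,
        imp_prob=0.0,
        imp_weights={},
        los_ward_median_days=10.0,
        los_icu_median_days=2.0,
        in_hospital_mortality_prob=0.0,
        discharge_transition_probs=(0.0, 1.0, 0.0),
        tm_alarm_prob_per_cycle=0.0,
        tm_intervention_success_prob=0.0,
        tm_facetoface_adaptation_prob=0.0,
        tm_contact_choice_probs=(1.0, 0.0, 0.0),
    )
    base.update(overrides)
    return NyhaParameters(**base)


def make_tariffs(**overrides) -> CostTariffs:
    base = dict(
        gp_visit_eur=25.0,
        specialist_visit_eur=31.0,
        ambulance_visit_eur=45.0,
        home_visit_eur=50.0,
        emergency_transport_eur=130.0,
        medication_event_eur=30.0,
        euro_per_ldf_point=1.0,
    )
    base.update(overrides)
    return CostTariffs(**base)


def make_ldf(**overrides) -> LdfGroup:
    base = dict(
        flat_points=1523.0,
        trim_min_days=4,
        trim_max_days=12,
        daily_supplement_points=100.0,
        reduced_flat_fraction=0.7,
        icu_daily_supplement_points=1248.0,
    )
    base.update(overrides)
    return LdfGroup(**base)


def make_config(arm: str = "conventional", params: dict | None = None, **overrides) -> ScenarioConfig:
    """A small, deterministic scenario; override per-class params via
    ``params`` (kwargs forwarded to :func:`make_params`)."""
    params = params or {}
    base = dict(
        name="test_scenario",
        arm=arm,
        n_patients=4,
        nyha_distribution=(0.0, 1.0, 0.0, 0.0),
        horizon_days=60,
        n_runs=1,
        seed=7,
        los_dispersion=0.0,
        nyha_params={k: make_params(**params) for k in (1, 2, 3, 4)},
        tariffs=make_tariffs(),
        ldf={k: make_ldf() for k in (1, 2, 3, 4)},
        imp_catalogue=[ImpCatalogueEntry(code="X1", points=5000.0)],
        toggles=Toggles(),
        financing=(
            TelemedFinancing(variant="A", monthly_rate_per_patient_eur=100.0)
            if arm == "telemedical"
            else None
        ),
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def make_patient(pid: int = 0, nyha: int = 2, status: str = "outpatient") -> PatientState:
    return PatientState(id=pid, nyha=nyha, status=status)


@pytest.fixture(scope="session")
def study_cfgs():
    """(conventional, TM variant A, TM variant B) packaged scenarios."""
    return study_default_scenarios()


@pytest.fixture()
def scenario_factory():
    return make_config


@pytest.fixture()
def params_factory():
    return make_params
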