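# Packaged study scenario (schema_version 1).
#
# Published inputs: median ward stay 10 / 6.5 days (conventional / telemedical),
# median ICU stay 2 days, per-6-month hospitalization risk 32.08% / 20.37%,
# routine GP visits 1.42 / 2.84 and specialist visits 0.3 / 0.46 per patient-year,
# ICU involvement 12.6% and in-hospital mortality 7.1% per admission; GP visit
# 25 EUR, specialist visit 31 EUR, in-hospital flat rate 1523 points within trim
# points 4-12 days, ICU supplement 1248 points/day (2496 EUR per median 2-day stay).
#
# ASSUMPTION (not published; see docs/methods.md): the branch probabilities of the
# outpatient pathways (emergency_prob_given_worsening, medication_change_prob,
# provider_choice_probs, improvement_prob_after_contact,
# hospitalization_prob_no_improvement, extramural_mortality_prob,
# discharge_transition_probs, tm_intervention_success_prob,
# tm_facetoface_adaptation_prob, tm_contact_choice_probs), imp_prob and the IMP
# catalogue, the ward daily_supplement_points, reduced_flat_fraction, and the
# ambulance/home-visit/transport/medication tariffs (all toggled off here).
# worsening_prob_per_day (conventional) and tm_alarm_prob_per_cycle (telemedical)
# are calibrated from the per-period hospitalization risk given those assumptions.
name: study_scenario_tm_b
arm: telemedical
n_patients: 100
nyha_distribution:
- 0.0
- 0.61
- 0.37
- 0.02
horizon_days: 1095
nyha_params:
  1:
    worsening_prob_per_day: 0.0
    emergency_prob_given_worsening: 0.3
    medication_change_prob: 0.3
    provider_choice_probs:
    - 0.4
    - 0.2
    - 0.1
    improvement_prob_after_contact: 0.8
    hospitalization_prob_no_improvement: 0.7
    extramural_mortality_prob: 0.02
    period_hospitalization_prob: 0.2037
    gp_visits_per_year: 2.84
    specialist_visits_per_year: 0.46
    icu_admission_prob: 0.126
    imp_prob: 0.1
    imp_weights:
      IMP-CARD-1: 1.0
    los_ward_median_days: 6.5
    los_icu_median_days: 2.0
    in_hospital_mortality_prob: 0.071
    discharge_transition_probs:
    - 0.3
    - 0.55
    - 0.15
    tm_alarm_prob_per_cycle: 0.021641718072454706
    tm_intervention_success_prob: 0.6
    tm_facetoface_adaptation_prob: 0.7
    tm_contact_choice_probs:
    - 0.4
    - 0.4
    - 0.2
  2:
    worsening_prob_per_day: 0.0
    emergency_prob_given_worsening: 0.3
    medication_change_prob: 0.3
    provider_choice_probs:
    - 0.4
    - 0.2
    - 0.1
    improvement_prob_after_contact: 0.8
    hospitalization_prob_no_improvement: 0.7
    extramural_mortality_prob: 0.02
    period_hospitalization_prob: 0.2037
    gp_visits_per_year: 2.84
    specialist_visits_per_year: 0.46
    icu_admission_prob: 0.126
    imp_prob: 0.1
    imp_weights:
      IMP-CARD-1: 1.0
    los_ward_median_days: 6.5
    los_icu_median_days: 2.0
    in_hospital_mortality_prob: 0.071
    discharge_transition_probs:
    - 0.3
    - 0.55
    - 0.15
    tm_alarm_prob_per_cycle: 0.021641718072454706
    tm_intervention_success_prob: 0.6
    tm_facetoface_adaptation_prob: 0.7
    tm_contact_choice_probs:
    - 0.4
    - 0.4
    - 0.2
  3:
    worsening_prob_per_day: 0.0
    emergency_prob_given_worsening: 0.3
    medication_change_prob: 0.3
    provider_choice_probs:
    - 0.4
    - 0.2
    - 0.1
    improvement_prob_after_contact: 0.8
    hospitalization_prob_no_improvement: 0.7
    extramural_mortality_prob: 0.02
    period_hospitalization_prob: 0.2037
    gp_visits_per_year: 2.84
    specialist_visits_per_year: 0.46
    icu_admission_prob: 0.126
    imp_prob: 0.1
    imp_weights:
      IMP-CARD-1: 1.0
    los_ward_median_days: 6.5
    los_icu_median_days: 2.0
    in_hospital_mortality_prob: 0.071
    discharge_transition_probs:
    - 0.3
    - 0.55
    - 0.15
    tm_alarm_prob_per_cycle: 0.021641718072454706
    tm_intervention_success_prob: 0.6
    tm_facetoface_adaptation_prob: 0.7
    tm_contact_choice_probs:
    - 0.4
    - 0.4
    - 0.2
  4:
    worsening_prob_per_day: 0.0
    emergency_prob_given_worsening: 0.3
    medication_change_prob: 0.3
    provider_choice_probs:
    - 0.4
    - 0.2
    - 0.1
    improvement_prob_after_contact: 0.8
    hospitalization_prob_no_improvement: 0.7
    extramural_mortality_prob: 0.02
    period_hospitalization_prob: 0.2037
    gp_visits_per_year: 2.84
    specialist_visits_per_year: 0.46
    icu_admission_prob: 0.126
    imp_prob: 0.1
    imp_weights:
      IMP-CARD-1: 1.0
    los_ward_median_days: 6.5
    los_icu_median_days: 2.0
    in_hospital_mortality_prob: 0.071
    discharge_transition_probs:
    - 0.3
    - 0.55
    - 0.15
    tm_alarm_prob_per_cycle: 0.021641718072454706
    tm_intervention_success_prob: 0.6
    tm_facetoface_adaptation_prob: 0.7
    tm_contact_choice_probs:
    - 0.4
    - 0.4
    - 0.2
tariffs:
  gp_visit_eur: 25.0
  specialist_visit_eur: 31.0
  ambulance_visit_eur: 45.0
  home_visit_eur: 50.0
  emergency_transport_eur: 130.0
  medication_event_eur: 30.0
  euro_per_ldf_point: 1.0
ldf:
  1:
    flat_points: 1523.0
    trim_min_days: 4
    trim_max_days: 12
    daily_supplement_points: 100.0
    reduced_flat_fraction: 0.7
    icu_daily_supplement_points: 1248.0
  2:
    flat_points: 1523.0
    trim_min_days: 4
    trim_max_days: 12
    daily_supplement_points: 100.0
    reduced_flat_fraction: 0.7
    icu_daily_supplement_points: 1248.0
  3:
    flat_points: 1523.0
    trim_min_days: 4
    trim_max_days: 12
    daily_supplement_points: 100.0
    reduced_flat_fraction: 0.7
    icu_daily_supplement_points: 1248.0
  4:
    flat_points: 1523.0
    trim_min_days: 4
    trim_max_days: 12
    daily_supplement_points: 100.0
    reduced_flat_fraction: 0.7
    icu_daily_supplement_points: 1248.0
imp_catalogue:
- code: IMP-CARD-1
  points: 5000.0
financing:
  variant: B
  monthly_rate_per_patient_eur: 0.0
  acquisition_per_system_eur: 1000.0
  monthly_overhead_eur: 500.0
  physician_fee_per_patient_month_eur: 40.0
toggles:
  ambulance_costs: false
  medication_costs: false
  transport_costs: false
  extramural_mortality: false
n_runs: 10
seed: 12345
reference_period_days: 182
hospitalization_counting: per_period_prob
los_dispersion: 0.5
schema_version: 1
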