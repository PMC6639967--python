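# Reference-case model inputs for community pharmacist- vs family physician-
# vs emergency physician-initiated management of uncomplicated UTI.
# Costs in 2018 CAD; probabilities and utilities as decimals.

cure_rate:
  pharmacist: 0.886
  family: 0.90
  emergency: 0.90

visit_cost:
  pharmacist: 23.00
  family_initial: 77.20
  family_followup: 38.35
  emergency: 304.80

initial_med_cost:
  pharmacist: 14.47
  family: 16.90
  emergency: 16.90

subsequent_med_cost:
  extend_pharmacist: 14.47
  extend_physician: 16.90
  switch_fluoroquinolone: 18.47

utility:
  baseline: 0.68
  cured_initial: 0.83
  persisted: 0.76
  cured_subsequent: 0.82

# probability a persistent patient extends the initial antibiotic rather
# than switching to a fluoroquinolone (structural assumption, not observed)
p_extend_vs_switch: 0.5

horizon_days: 30
initial_window_days: 14
subsequent_window_days: 16

structure:
  followup_provider:
    pharmacist: pharmacist
    family: family_followup
    emergency: family_followup
  persisted_cured_days: 0

societal:
  hourly_wage: 22.97
  hours_family_visit: 4
  hours_ed_visit: 8
  parking_rate_per_hour: 1.75
  transit_fare_one_way: 2.75
  transport_mode:
    pharmacist: transit
    family: transit
    emergency: parking
  work_loss_hours:
    pharmacist: 0
    family: 4
    emergency: 8
  followup_addons: true

bia:
  year1_population: 1614384
  growth_rate: 0.01
  n_years: 5
  current_uptake: 0.01
  target_uptake: 0.25
  # emergency share calibrated so the year-1 current-scenario per-patient
  # cost matches the published reference projection (242,003,570 over
  # 1,614,384 patients at the mean per-patient costs below)
  provider_mix:
    family: 0.959596
    emergency: 0.040404
  per_patient_cost:
    pharmacist: 72.47
    family: 141.53
    emergency: 368.16
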