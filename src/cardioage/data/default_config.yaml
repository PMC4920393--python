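# Default study configuration: a normal 20-year-old operating point and the
# per-decade arterial aging schedule.  All values can be overridden by a user
# config file with the same structure.
cardiac:
  ees_mmhg_per_ml: 1.0          # end-systolic elastance
  eed_mmhg_per_ml: 0.025        # end-diastolic elastance
  ped_target_mmhg: 5.0          # calibrated end-diastolic LV pressure
  period_s: 0.89                # R-R interval (heart rate 67 /min)
  v0_ml: 0.0                    # unstressed volume; volumes reported relative to it
  shape:                        # double-Hill activation, fractions of the cycle
    rise_exponent: 1.2
    rise_timescale: 0.26
    decay_exponent: 40.0
    decay_timescale: 0.46
arterial:
  # Linear endpoints for compliance (mL/mmHg) and resistance (mmHg·s/mL),
  # constant inertance (mmHg·s²/mL), tabulated characteristic impedance.
  c_age20: 2.8
  c_age80: 0.7
  r_age20: 0.8
  r_age80: 1.04
  inertance: 0.005
  zc_by_age: {20: 0.020, 30: 0.021, 40: 0.023, 50: 0.025, 60: 0.028, 70: 0.033, 80: 0.040}
valves:
  resistance_mmhg_s_per_ml: 0.003
  inertance_mmhg_s2_per_ml: 3.0e-5
solver:
  dt_s: 2.0e-4                  # RK4 step
  max_beats: 100
  sv_tol_ml: 0.1                # beat-to-beat steady-state tolerances
  pressure_tol_mmhg: 0.1
  adaptation_max_iter: 50
  adaptation_psys_tol_mmhg: 1.0
  adaptation_edv_tol_ml: 1.0
comparison:
  reference_csv: null           # optional (age_years, sys_mmHg, dia_mmHg) CSV
  # additive central->brachial systolic amplification per decade, mmHg
  amplification_by_age: {20: 0.0, 30: 0.0, 40: 0.0, 50: 0.0, 60: 0.0, 70: 0.0, 80: 0.0}
output:
  directory: cardioage_out
seed: 0
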