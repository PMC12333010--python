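# Example run configuration for the thcpd CLI.
#
#   thcpd simulate      --config examples/run.yaml --out out/sim
#   thcpd dose-response --config examples/run.yaml --out out/dr --doses 1cig,5cig,10cig --routes inhaled
#   thcpd synth         --config examples/run.yaml --out out/synth
#   thcpd verify        --config examples/run.yaml --out out/ver --observed out/synth/observed.csv
#
# Omitted sections fall back to the package defaults: the documented
# desk-scale PK fixture and the population PD parameters.

compounds:
  parent:
    name: THC
    molar_mass: 314.46
    f_a: 0.45          # oral fraction absorbed
    k_a: 0.7           # 1/h
    lung_f_a: 0.6      # inhaled fraction absorbed (study-specific)
    lung_k_a: 200.0    # 1/h
  metabolite:
    name: 11-OH-THC
    molar_mass: 330.46

feeling_high:
  k_e0_thc: 2.0
  k_e0_11oh: 2.0
  e_max: 80.0          # mm
  ec50: 0.21           # uM
  hill: 1.8
  cv_emax: 34.0        # %
  cv_ec50: 70.0        # %

alertness:
  k_out: 1.0           # 1/h
  baseline: 60.0       # mm
  e_max_pct: 90.0      # % maximal inhibition of k_in
  ec50: 0.23           # uM
  hill: 1.9
  cv_emax: 30.0
  cv_ec50: 30.0

design:
  regimen:
    - route: inhaled
      amount_mg: 10.0
      start_time: 0.0
  sampling: {t_end: 12.0, step: 0.05}
  n_trials: 20
  n_subjects_per_trial: 25
  baseline_alertness: 60.0
  seed: 2024
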