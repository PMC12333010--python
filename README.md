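# thcpd

PBPK–PD simulation of the psychoactive effects of Δ9-tetrahydrocannabinol
(THC): a perfusion-limited physiologically based pharmacokinetic engine
for THC and its active metabolite 11-OH-THC coupled to two
pharmacodynamic models of subjective effect measured on 0–100 mm visual
analogue scales (VAS) — **feeling high** and **alertness** — plus
virtual-trial population simulation, verification statistics, and
parameter estimation with recovery studies.

It is aimed at pharmacometricians and cannabinoid researchers who want a
scriptable, reproducible desk-scale counterpart to commercial PBPK–PD
workflows: every stage (PK → PD → population → verification → fitting)
is a plain Python function operating on plain containers, and synthetic
observed studies let the whole pipeline run with no external data.

## The models

**PK.** A closed-loop whole-body circuit (venous blood → lung → arterial
blood → brain / liver / rest-of-body → venous blood) with
perfusion-limited tissues,

```
V_t dC_t/dt = Q_t (C_art − C_t·BP/Kp_t),
```

first-order oral absorption into the portal inflow (f_a = 0.45,
k_a = 0.7 h⁻¹, giving first-pass extraction), first-order pulmonary
absorption of inhaled doses (Lung f_a, Lung k_a), IV bolus/infusion, and
hepatic elimination with a fixed molar fraction of cleared THC forming
11-OH-THC. Kinetics are linear in dose.

**Feeling high** (direct model, baseline 0 mm). Each compound's total
brain concentration drives an effect compartment,
`dC_e/dt = k_e0 (C_brain − C_e)` with k_e0 = 2 h⁻¹, and the score is a
sigmoid Emax function of the *summed* effect-site concentrations (the
compounds are assumed equipotent):

```
VAS_high = E_max · S^h / (EC50^h + S^h),   S = C_THC,e + C_11OH,e
```

with E_max = 80 mm, EC50 = 0.21 µM, h = 1.8.

**Alertness** (indirect/turnover model, baseline 60 mm). Zero-order
production k_in = Baseline · k_out (k_out = 1 h⁻¹) is inhibited by an
Emax function of the summed *brain* concentrations (no effect
compartment — the turnover supplies the lag): maximal inhibition 90%,
EC50 = 0.23 µM, h = 1.9.

**Population.** Virtual subjects draw Emax and EC50 per endpoint from
median-anchored log-normal distributions at the configured CVs
(34%/70% for feeling high, 30%/30% for alertness); the default design is
20 trials × 25 adults, single dose, seeded end-to-end.

## Worked example

```
$ python examples/single_dose_profile.py
plasma THC  Cmax 0.114 uM at t = 0.05 h
brain THC   Cmax 1.160 uM at t = 0.05 h
post-distribution brain:plasma ratio at 2 h: 3.6x (2-5x expected)
feeling high peaks at 51.8 mm at t = 0.40 h (lags brain Cmax: effect-compartment hysteresis)
alertness troughs at 41.1 mm (from 60 mm baseline) at t = 1.35 h
```

A 10 mg inhaled dose is absorbed within minutes; brain THC equilibrates
to a few-fold excess over plasma; the subjective high peaks ~0.4 h after
exposure because the effect compartment lags the brain, and alertness
reaches its minimum later still because the turnover pool empties with a
1 h⁻¹ time constant. Other examples, one per capability:

- `examples/virtual_trial.py` — 500-subject replicated trial with the
  5th–95th percentile band
- `examples/dose_response.py` — 1–100 mg oral and inhaled sweeps,
  including the 1/5/10-cannabis-cigarette doses (2.55/12.75/25.5 mg)
- `examples/fit_recovery.py` — estimate Emax, EC50, k_e0 from a noisy
  synthetic study and compare with the generating truth
- `examples/verify_synthetic.py` — R_max fold checks and percentile
  coverage on a synthetic study batch

The same stages are exposed as a thin CLI
(`thcpd simulate|dose-response|verify|fit|synth --config run.yaml --out dir`)
driven by one YAML document per run; outputs are unit-suffixed CSVs plus
a manifest carrying the seed and config hash.

Note: the shipped PK parameterization is a documented desk-scale fixture
tuned only to coarse public properties of THC disposition (see
`docs/methods.md`); it is configurable and not an authoritative
physiological dataset.

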