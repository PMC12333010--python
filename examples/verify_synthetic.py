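"""Verification statistics on a batch of synthetic observed trials.

Generates synthetic observed feeling-high studies across several doses
and routes, simulates the matching virtual-trial designs, and reports the
fold-range (R_max) checks and percentile coverage — the same statistics
used to judge predictions against digitized clinical curves.
"""

import numpy as np

from thcpd import (
    OH_THC,
    THC,
    TrialDesign,
    SyntheticStudySpec,
    default_pk_fixture,
    generate_observed_study,
    run_virtual_study,
    single_dose_regimen,
    verify_batch,
)

pk = default_pk_fixture()
compounds = (THC, OH_THC)
grid = np.round(np.arange(0.0, 8.0001, 0.1), 10)

pairs = []
for i, (dose, route) in enumerate([(2.0, "inhaled"), (10.0, "inhaled"),
                                   (25.5, "inhaled"), (20.0, "oral"),
                                   (50.0, "oral")]):
    regimen = single_dose_regimen(dose, route)
    observed, _ = generate_observed_study(SyntheticStudySpec(
        regimen=regimen, sampling_times=grid, noise_sd=3.0, n_subjects=25,
        seed=100 + i, label=f"{route}-{dose:g}mg", pk_spec=pk,
        compounds=compounds))
    design = TrialDesign(regimen=regimen, sampling_times=grid, n_trials=20,
                         n_subjects_per_trial=25, seed=900 + i)
    summary = run_virtual_study(design, pk, compounds, "feeling_high").summary
    pairs.append((observed, summary))

report = verify_batch(pairs)
print(report.summary_text())
print("\nR_max is the predicted:observed peak ratio; a trial passes if it")
print("lies within 2-fold (feeling high). Coverage is the share of observed")
print("points inside the predicted 5th-95th percentile band.")
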