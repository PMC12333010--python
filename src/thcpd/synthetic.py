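"""Synthetic "observed" VAS studies for verification and estimation.

Real verification data for this kind of model are digitized mean VAS
curves from clinical trials.  This module emulates their statistical
structure so every downstream stage runs self-contained: the population
mean trajectory is forward-simulated from known true parameters (with
interindividual variability across the synthetic subjects), additive
Gaussian observation noise is applied to the mean, and the result is
clipped to the 0-100 mm scale.  The generating truth is emitted alongside
for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .params import AlertnessParams, CompoundParams, FeelingHighParams, OH_THC, THC
from .pk import DoseEvent, PKModelSpec, default_pk_fixture, simulate_pk
from .population import TrialDesign, run_virtual_study
from .series import ObservedSeries


def clinical_sampling_grid(t_end: float = 8.0) -> np.ndarray:
    """Clinical-style grid: every 10 min to 2 h, then hourly to ``t_end``."""
    early = np.arange(0.0, 2.0001, 1.0 / 6.0)
    late = np.arange(3.0, t_end + 1e-9, 1.0)
    return np.round(np.unique(np.concatenate([early, late])), 10)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Configuration of one synthetic observed study."""

    regimen: tuple[DoseEvent, ...]
    endpoint: str = "feeling_high"
    high: FeelingHighParams = field(default_factory=FeelingHighParams)
    alert: AlertnessParams = field(default_factory=AlertnessParams)
    pk_spec: PKModelSpec = field(default_factory=default_pk_fixture)
    compounds: tuple[CompoundParams, CompoundParams] = (THC, OH_THC)
    sampling_times: np.ndarray = field(default_factory=clinical_sampling_grid)
    noise_sd: float = 3.0  # mm, additive Gaussian on the mean curve
    n_subjects: int = 25  # subjects contributing to the observed mean
    with_iiv: bool = True
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimen", tuple(self.regimen))
        t = np.asarray(self.sampling_times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be a strictly increasing grid")
        object.__setattr__(self, "sampling_times", t)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def ground_truth(spec: SyntheticStudySpec) -> dict:
    """The generating parameters, for round-trip recovery tests."""
    p = spec.high if spec.endpoint == "feeling_high" else spec.alert
    truth = {"endpoint": spec.endpoint, "seed": spec.seed,
             "noise_sd_mm": spec.noise_sd, "n_subjects": spec.n_subjects}
    if spec.endpoint == "feeling_high":
        truth.update(e_max=p.e_max, ec50=p.ec50, hill=p.hill, k_e0=p.k_e0_thc)
    else:
        truth.update(e_max_pct=p.e_max_pct, ec50=p.ec50, hill=p.hill,
                     k_out=p.k_out, baseline=p.baseline)
    return truth


def generate_observed_study(
    spec: SyntheticStudySpec,
) -> tuple[ObservedSeries, dict]:
    """Forward-simulate one study and return (observed series, truth).

    With ``with_iiv`` the mean is taken across ``n_subjects`` virtual
    subjects sampled at the configured CVs; otherwise the deterministic
    population-parameter trajectory is used.  Noise and IIV draws are both
    controlled by ``spec.seed``.
    """
    high = spec.high
    alert = spec.alert
    if not spec.with_iiv:
        high = replace(high, cv_emax=0.0, cv_ec50=0.0)
        alert = replace(alert, cv_emax=0.0, cv_ec50=0.0)
    design = TrialDesign(
        regimen=spec.regimen,
        sampling_times=spec.sampling_times,
        n_trials=1,
        n_subjects_per_trial=spec.n_subjects,
        baseline_alertness=alert.baseline,
        seed=spec.seed,
    )
    result = run_virtual_study(design, spec.pk_spec, spec.compounds,
                               spec.endpoint, pop_high=high, pop_alert=alert)
    mean = result.summary.mean
    # observation noise is seeded independently of the IIV stream
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x0b5]))
    noisy = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    observed = ObservedSeries(
        times=spec.sampling_times,
        mean_vas=np.clip(noisy, 0.0, 100.0),
        sd=None,
        n=spec.n_subjects,
        endpoint=spec.endpoint,
        trial=spec.label,
        dose_mg=sum(ev.amount_mg for ev in spec.regimen),
        route=spec.regimen[0].route if spec.regimen else None,
    )
    return observed, ground_truth(spec)


def make_two_peak_oral_series(
    spec: SyntheticStudySpec,
    meal_time: float,
    meal_boost: float,
) -> tuple[ObservedSeries, dict]:
    """Stress fixture: an oral study with a meal-driven second absorption phase.

    A delayed oral depot of ``meal_boost`` times the original dose is
    added at ``meal_time``, producing the two-peak mean curve seen in
    long oral studies with post-dose meals.  The single-dose model is not
    meant to fit this shape; the fixture exists to exercise the
    verification statistics under structural mismatch.
    """
    if not (spec.sampling_times[0] <= meal_time <= spec.sampling_times[-1]):
        raise ValueError("meal_time lies outside the sampling span")
    if meal_boost < 0:
        raise ValueError("meal_boost must be >= 0")
    if meal_boost == 0:
        return generate_observed_study(spec)
    total_oral = sum(ev.amount_mg for ev in spec.regimen if ev.route == "oral")
    if total_oral == 0:
        raise ValueError("two-peak fixture requires an oral dose")
    extra = DoseEvent(route="oral", amount_mg=meal_boost * total_oral,
                      start_time=meal_time)
    boosted = replace(spec, regimen=spec.regimen + (extra,),
                      label=f"{spec.label}+meal")
    return generate_observed_study(boosted)


def study_batch(
    doses_mg: Sequence[float],
    routes: Sequence[str],
    base: SyntheticStudySpec,
) -> list[tuple[ObservedSeries, dict]]:
    """One synthetic study per (dose, route) pair, seeds split from the base."""
    out = []
    for i, (dose, route) in enumerate(zip(doses_mg, routes)):
        duration = 0.25 if route == "iv_infusion" else 0.0
        spec = replace(
            base,
            regimen=(DoseEvent(route=route, amount_mg=dose, duration=duration),),
            seed=base.seed + i + 1,
            label=f"{base.label}-{route}-{dose:g}mg",
        )
        out.append(generate_observed_study(spec))
    return out
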