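"""Synthetic observed-study generation."""

import numpy as np
import pytest

from thcpd import (
    DoseEvent,
    SyntheticStudySpec,
    clinical_sampling_grid,
    generate_observed_study,
    make_two_peak_oral_series,
    simulate_feeling_high,
    simulate_pk,
    single_dose_regimen,
    study_batch,
    FeelingHighParams,
)


def test_noiseless_no_iiv_equals_deterministic(pk_spec, compounds):
    """noise sd 0 + CVs 0 reproduces the forward model output exactly."""
    reg = single_dose_regimen(10.0, "inhaled")
    grid = clinical_sampling_grid(8.0)
    obs, truth = generate_observed_study(SyntheticStudySpec(
        regimen=reg, noise_sd=0.0, with_iiv=False, n_subjects=1,
        sampling_times=grid, pk_spec=pk_spec, compounds=compounds))
    conc = simulate_pk(pk_spec, compounds, reg, grid)
    direct = simulate_feeling_high(conc, FeelingHighParams())
    assert obs.mean_vas == pytest.approx(direct.vas, abs=1e-9)
    assert truth["e_max"] == 80.0 and truth["ec50"] == 0.21


def test_zero_dose_alertness_is_flat_baseline(pk_spec, compounds):
    obs, _ = generate_observed_study(SyntheticStudySpec(
        regimen=(DoseEvent("oral", 0.0),), endpoint="alertness",
        noise_sd=0.0, n_subjects=5, pk_spec=pk_spec, compounds=compounds))
    assert obs.mean_vas == pytest.approx(np.full_like(obs.times, 60.0), abs=1e-6)


def test_noise_is_seeded_and_clipped(pk_spec, compounds):
    spec = SyntheticStudySpec(regimen=single_dose_regimen(10.0, "inhaled"),
                              noise_sd=3.0, n_subjects=10, seed=21,
                              pk_spec=pk_spec, compounds=compounds)
    a, _ = generate_observed_study(spec)
    b, _ = generate_observed_study(spec)
    assert np.array_equal(a.mean_vas, b.mean_vas)
    assert np.all((a.mean_vas >= 0) & (a.mean_vas <= 100))
    c, _ = generate_observed_study(
        SyntheticStudySpec(regimen=spec.regimen, noise_sd=3.0, n_subjects=10,
                           seed=22, pk_spec=pk_spec, compounds=compounds))
    assert not np.array_equal(a.mean_vas, c.mean_vas)


def test_batch_emulates_design_diversity(pk_spec, compounds):
    """16 regimens across 2-86 mg and three routes, all schema-valid."""
    rng = np.random.default_rng(2)
    doses = np.round(rng.uniform(2.0, 86.0, 16), 1)
    routes = [["oral", "inhaled", "iv_infusion"][i % 3] for i in range(16)]
    base = SyntheticStudySpec(regimen=single_dose_regimen(10.0, "oral"),
                              n_subjects=8, pk_spec=pk_spec,
                              compounds=compounds, seed=77)
    batch = study_batch(doses, routes, base)
    assert len(batch) == 16
    for obs, truth in batch:
        df = obs.to_frame()
        assert list(df.columns)[:2] == ["time_h", "vas_mm"]
        assert df["vas_mm"].between(0, 100).all()
        assert truth["endpoint"] == "feeling_high"


class TestTwoPeak:
    def test_zero_boost_identical(self, pk_spec, compounds):
        spec = SyntheticStudySpec(regimen=single_dose_regimen(20.0, "oral"),
                                  noise_sd=0.0, with_iiv=False, n_subjects=1,
                                  sampling_times=clinical_sampling_grid(12.0),
                                  pk_spec=pk_spec, compounds=compounds)
        plain, _ = generate_observed_study(spec)
        boosted, _ = make_two_peak_oral_series(spec, meal_time=3.0, meal_boost=0.0)
        assert np.array_equal(plain.mean_vas, boosted.mean_vas)

    def test_meal_creates_second_peak(self, pk_spec, compounds):
        grid = np.round(np.arange(0.0, 12.001, 0.25), 10)
        spec = SyntheticStudySpec(regimen=single_dose_regimen(20.0, "oral"),
                                  noise_sd=0.0, with_iiv=False, n_subjects=1,
                                  sampling_times=grid, pk_spec=pk_spec,
                                  compounds=compounds)
        obs, _ = make_two_peak_oral_series(spec, meal_time=3.0, meal_boost=0.5)
        v = obs.mean_vas
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        assert interior.sum() == 2

    def test_meal_time_outside_span_rejected(self, pk_spec, compounds):
        spec = SyntheticStudySpec(regimen=single_dose_regimen(20.0, "oral"),
                                  pk_spec=pk_spec, compounds=compounds)
        with pytest.raises(ValueError):
            make_two_peak_oral_series(spec, meal_time=50.0, meal_boost=0.5)

    def test_two_peak_series_hurts_coverage(self, pk_spec, compounds):
        """Against a single-peak model band, the meal series is covered
        strictly worse than the matching no-meal series."""
        from thcpd import TrialDesign, percentile_coverage, run_virtual_study

        grid = np.round(np.arange(0.0, 12.001, 0.25), 10)
        spec = SyntheticStudySpec(regimen=single_dose_regimen(20.0, "oral"),
                                  noise_sd=0.0, with_iiv=False, n_subjects=1,
                                  sampling_times=grid, pk_spec=pk_spec,
                                  compounds=compounds)
        plain, _ = generate_observed_study(spec)
        meal, _ = make_two_peak_oral_series(spec, meal_time=3.0, meal_boost=1.0)
        design = TrialDesign(regimen=spec.regimen, sampling_times=grid,
                             n_trials=2, n_subjects_per_trial=25, seed=31)
        band = run_virtual_study(design, pk_spec, compounds, "feeling_high").summary
        assert (percentile_coverage(meal, band)
                < percentile_coverage(plain, band))
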