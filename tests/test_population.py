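"""Virtual-subject sampling and replicated-trial simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thcpd import (
    AlertnessParams,
    FeelingHighParams,
    TrialDesign,
    dose_response_curve,
    run_virtual_study,
    sample_subject,
    simulate_feeling_high,
    single_dose_regimen,
    summarize,
)


class TestSampling:
    def test_zero_cv_returns_population_values(self):
        high = FeelingHighParams(cv_emax=0.0, cv_ec50=0.0)
        alert = AlertnessParams(cv_emax=0.0, cv_ec50=0.0)
        s = sample_subject(high, alert, np.random.default_rng(0))
        assert s.high.e_max == high.e_max and s.high.ec50 == high.ec50
        assert s.alert.e_max_pct == alert.e_max_pct and s.alert.ec50 == alert.ec50

    def test_lognormal_cv_and_positivity(self):
        """1e5 draws at CV 70% reproduce the target CV and never go <= 0."""
        high, alert = FeelingHighParams(), AlertnessParams()
        rng = np.random.default_rng(123)
        draws = np.array([
            sample_subject(high, alert, rng).high.ec50 for _ in range(100_000)
        ])
        assert np.all(draws > 0)
        cv = draws.std(ddof=1) / draws.mean()
        assert 0.68 <= cv <= 0.72

    def test_median_anchoring(self):
        """Median-preserving parameterization: half the Emax draws exceed
        the population value."""
        high, alert = FeelingHighParams(), AlertnessParams()
        rng = np.random.default_rng(7)
        frac = np.mean([
            sample_subject(high, alert, rng).high.e_max > high.e_max
            for _ in range(100_000)
        ])
        assert frac == pytest.approx(0.5, abs=0.01)

    @given(cv=st.floats(1.0, 120.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_positivity_for_any_cv(self, cv):
        high = FeelingHighParams(cv_emax=cv, cv_ec50=cv)
        s = sample_subject(high, AlertnessParams(), np.random.default_rng(11))
        assert s.high.e_max > 0 and s.high.ec50 > 0


class TestVirtualStudy:
    def test_single_subject_no_cv_equals_deterministic(self, pk_spec, compounds,
                                                       grid_12h):
        design = TrialDesign(regimen=single_dose_regimen(10.0, "inhaled"),
                             sampling_times=grid_12h, n_trials=1,
                             n_subjects_per_trial=1, seed=3)
        high = FeelingHighParams(cv_emax=0.0, cv_ec50=0.0)
        res = run_virtual_study(design, pk_spec, compounds, "feeling_high",
                                pop_high=high)
        direct = simulate_feeling_high(res.conc, high)
        assert res.trajectories.shape == (1, grid_12h.size)
        assert res.trajectories[0] == pytest.approx(direct.vas, abs=1e-9)
        assert res.summary.mean == pytest.approx(direct.vas, abs=1e-9)

    def test_seed_reproducibility(self, small_design, pk_spec, compounds):
        a = run_virtual_study(small_design, pk_spec, compounds, "alertness")
        b = run_virtual_study(small_design, pk_spec, compounds, "alertness")
        assert np.array_equal(a.trajectories, b.trajectories)

    def test_variability_band(self, small_design, pk_spec, compounds):
        """IIV acts on the PD response: the p5-p95 band is wide at peak and
        collapses at t=0 where the baseline is common to all subjects."""
        res = run_virtual_study(small_design, pk_spec, compounds, "feeling_high")
        width = res.summary.p95 - res.summary.p5
        assert width[np.argmax(res.summary.mean)] > 0.0
        assert width[0] < 1.0

    def test_summary_consistent_with_subject_table(self, small_design, pk_spec,
                                                   compounds):
        res = run_virtual_study(small_design, pk_spec, compounds, "feeling_high")
        df = res.to_frame()
        wide = df.pivot_table(index="subject_id", columns="time_h",
                              values="vas_mm").to_numpy()
        re_sum = summarize(res.times, wide)
        assert re_sum.mean == pytest.approx(res.summary.mean)
        assert re_sum.p5 == pytest.approx(res.summary.p5)
        assert re_sum.p95 == pytest.approx(res.summary.p95)

    def test_percentile_order(self, small_design, pk_spec, compounds):
        res = run_virtual_study(small_design, pk_spec, compounds, "alertness")
        assert np.all(res.summary.p5 <= res.summary.p95)
        assert np.all(res.summary.mean >= res.trajectories.min(axis=0))
        assert np.all(res.summary.mean <= res.trajectories.max(axis=0))


class TestDoseResponse:
    def test_zero_dose_extremes(self, small_design, pk_spec, compounds):
        high = dose_response_curve([0.0], "oral", small_design, pk_spec,
                                   compounds, "feeling_high")
        alert = dose_response_curve([0.0], "oral", small_design, pk_spec,
                                    compounds, "alertness")
        assert high["mean_mm"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert alert["mean_mm"].iloc[0] == pytest.approx(60.0, abs=1e-6)

    def test_oral_5_vs_50_mg(self, small_design, pk_spec, compounds):
        """Minimal effect below 5 mg oral, substantial by 50 mg."""
        df = dose_response_curve([5.0, 50.0], "oral", small_design, pk_spec,
                                 compounds, "feeling_high")
        assert df["mean_mm"].iloc[1] > df["mean_mm"].iloc[0]
        assert df["mean_mm"].iloc[0] < 10.0

    def test_inhaled_peak_earlier_than_oral(self, small_design, pk_spec,
                                            compounds):
        times = {}
        for route in ("oral", "inhaled"):
            res = run_virtual_study(
                small_design.with_regimen(single_dose_regimen(20.0, route)),
                pk_spec, compounds, "feeling_high")
            times[route] = res.times[np.argmax(res.summary.mean)]
        assert times["inhaled"] < times["oral"]

    def test_empty_dose_list_rejected(self, small_design, pk_spec, compounds):
        with pytest.raises(ValueError):
            dose_response_curve([], "oral", small_design, pk_spec, compounds,
                                "feeling_high")
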