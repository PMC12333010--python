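"""PK engine: unit conversions, absorption kinetics, mass balance, linearity."""

import numpy as np
import pytest

from thcpd import (
    CompoundParams,
    ConfigurationError,
    DoseEvent,
    InvalidParameterError,
    OH_THC,
    PKModelSpec,
    THC,
    Tissue,
    absorption_rate,
    dose_to_amount,
    simulate_pk,
)


@pytest.mark.parametrize("mg, mm, expected, tol", [
    (0.0, 314.46, 0.0, 0.0),
    (314.46, 314.46, 1000.0, 1e-9),
    (2.55, 314.46, 8.109, 1e-3),  # one cigarette's THC in umol
])
def test_dose_to_amount(mg, mm, expected, tol):
    assert dose_to_amount(mg, mm) == pytest.approx(expected, abs=tol)


def test_dose_to_amount_rejects_bad_inputs():
    with pytest.raises(InvalidParameterError):
        dose_to_amount(1.0, 0.0)
    with pytest.raises(InvalidParameterError):
        dose_to_amount(-1.0, 314.46)


class TestAbsorptionRate:
    def test_oral_first_order(self):
        ev = DoseEvent("oral", 10.0)
        assert absorption_rate(ev, THC, depot_amount=10.0, t=1.0) == pytest.approx(7.0)

    def test_empty_depot(self):
        assert absorption_rate(DoseEvent("oral", 10.0), THC, 0.0, 1.0) == 0.0

    def test_zero_before_start(self):
        ev = DoseEvent("oral", 10.0, start_time=2.0)
        assert absorption_rate(ev, THC, 5.0, 1.0) == 0.0

    def test_infusion_window(self):
        ev = DoseEvent("iv_infusion", 3.1446, start_time=0.0, duration=0.5)
        rate = absorption_rate(ev, THC, 0.0, 0.25)
        assert rate == pytest.approx(dose_to_amount(3.1446, 314.46) / 0.5)
        assert absorption_rate(ev, THC, 0.0, 0.75) == 0.0

    def test_unknown_route_rejected(self):
        with pytest.raises(ConfigurationError):
            DoseEvent("sublingual", 10.0)


def test_inhaled_depot_first_order_decay(pk_spec, compounds):
    """Lung depot decays as lung_f_a * dose * exp(-lung_k_a t); >99% absorbed
    by t = 0.025 h at lung_k_a = 200/h."""
    times = np.linspace(0, 0.05, 51)
    dose = 2.55
    _, sol = simulate_pk(pk_spec, compounds, [DoseEvent("inhaled", dose)],
                         times, full_output=True)
    d0 = THC.lung_f_a * dose_to_amount(dose, THC.molar_mass)
    expected = d0 * np.exp(-THC.lung_k_a * times)
    assert sol.depot_lung[1:] == pytest.approx(expected[1:], rel=1e-5)
    i = np.searchsorted(times, 0.025)
    assert sol.depot_lung[i] < 0.01 * d0


def test_zero_dose_is_identically_zero(pk_spec, compounds, grid_12h):
    series = simulate_pk(pk_spec, compounds, [], grid_12h)
    for c in series.compounds:
        assert np.all(series.plasma[c] == 0.0)
        assert np.all(series.brain[c] == 0.0)


def test_one_compartment_iv_bolus_matches_analytic(compounds):
    """Degenerate single-tissue model: C(t) = D/V * exp(-CL/V t)."""
    v, cl, dose_mg = 40.0, 10.0, 314.46
    spec = PKModelSpec.one_compartment(volume=v, clearance=cl)
    t = np.linspace(0, 12, 241)
    series = simulate_pk(spec, compounds, [DoseEvent("iv_bolus", dose_mg)], t)
    d_umol = dose_to_amount(dose_mg, compounds[0].molar_mass)
    analytic = d_umol / v * np.exp(-cl / v * t)
    rel = np.abs(series.plasma["THC"][1:] - analytic[1:]) / analytic[1:]
    assert rel.max() < 1e-6


@pytest.mark.parametrize("regimen", [
    [DoseEvent("iv_bolus", 5.0)],
    [DoseEvent("iv_infusion", 5.0, duration=0.25)],
    [DoseEvent("oral", 20.0)],
    [DoseEvent("inhaled", 10.0)],
    [DoseEvent("oral", 10.0), DoseEvent("inhaled", 5.0, start_time=2.0)],
], ids=["bolus", "infusion", "oral", "inhaled", "mixed"])
def test_mass_balance_within_0p1pct(pk_spec, compounds, grid_12h, regimen):
    _, sol = simulate_pk(pk_spec, compounds, regimen, grid_12h, full_output=True)
    assert sol.mass_balance_error() < 1e-3


@pytest.mark.parametrize("route", ["iv_bolus", "oral", "inhaled"])
def test_dose_linearity(pk_spec, compounds, route):
    """Doubling the dose doubles every concentration (linear kinetics)."""
    t = np.linspace(0, 8, 81)
    lo = simulate_pk(pk_spec, compounds, [DoseEvent(route, 5.0)], t)
    hi = simulate_pk(pk_spec, compounds, [DoseEvent(route, 10.0)], t)
    for c in lo.compounds:
        for attr in ("plasma", "brain"):
            a, b = getattr(lo, attr)[c], getattr(hi, attr)[c]
            mask = a > a.max() * 1e-9
            assert np.abs(b[mask] / a[mask] - 2.0).max() < 1e-6


def test_route_equivalence_in_one_compartment_limit(compounds):
    """With f_a = 1 and k_a -> inf, extravascular routes converge to the IV
    bolus profile (checked where every route feeds the same compartment)."""
    spec = PKModelSpec.one_compartment(volume=40.0, clearance=10.0)
    fast = CompoundParams(name="THC", molar_mass=314.46, f_a=1.0, k_a=1e4,
                          lung_f_a=1.0, lung_k_a=1e4)
    t = np.linspace(0, 12, 1201)
    iv = simulate_pk(spec, (fast, OH_THC), [DoseEvent("iv_bolus", 10.0)], t)
    auc_iv = np.trapezoid(iv.plasma["THC"], t)
    for route in ("oral", "inhaled"):
        ev = simulate_pk(spec, (fast, OH_THC), [DoseEvent(route, 10.0)], t)
        auc = np.trapezoid(ev.plasma["THC"], t)
        assert auc == pytest.approx(auc_iv, rel=0.02)


def test_brain_to_plasma_ratio_2_to_5_fold(inhaled_conc):
    """Post-distribution total brain THC runs 2-5x the plasma level."""
    t = inhaled_conc.times
    mask = t >= 1.0
    ratio = inhaled_conc.brain["THC"][mask] / inhaled_conc.plasma["THC"][mask]
    assert ratio.min() > 2.0 and ratio.max() < 5.0


def test_solver_tolerance_refinement(pk_spec, compounds, grid_12h):
    """Halving solver tolerances moves the peak brain concentration <0.1%."""
    reg = [DoseEvent("oral", 20.0)]
    a = simulate_pk(pk_spec, compounds, reg, grid_12h)
    b = simulate_pk(pk_spec, compounds, reg, grid_12h, rtol=5e-9, atol=5e-11)
    pa, pb = a.brain["THC"].max(), b.brain["THC"].max()
    assert abs(pa - pb) / pb < 1e-3


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        DoseEvent("oral", -1.0)
    with pytest.raises(ConfigurationError):
        # flows that do not sum to cardiac output
        PKModelSpec(
            cardiac_output=390.0,
            tissues=(
                Tissue("brain", 1.45, 45.0, 3.5, 3.5),
                Tissue("liver", 1.8, 90.0, 10.0, 5.0),
                Tissue("rest", 62.0, 200.0, 3.0, 1.5),
            ),
        )
    with pytest.raises(ConfigurationError):
        # missing liver
        PKModelSpec(
            cardiac_output=100.0,
            tissues=(Tissue("brain", 1.45, 100.0, 3.5, 3.5),),
        )


def test_metabolite_is_formed_and_cleared(oral_conc):
    """Oral first pass produces measurable 11-OH-THC alongside parent."""
    m = oral_conc.plasma["11-OH-THC"]
    assert m.max() > 0
    # metabolite washes out by the end of the window
    assert m[-1] < 0.5 * m.max()
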