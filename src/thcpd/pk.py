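"""Perfusion-limited PBPK engine for THC and its active metabolite.

The model is a closed-loop whole-body circuit: venous blood -> lung ->
arterial blood -> perfused tissues (brain, liver, rest-of-body by default,
extensible) -> venous blood.  Each tissue is perfusion limited,

    V_t dC_t/dt = Q_t (C_art - C_t * BP / Kp_t),

with ``C_t`` the total tissue concentration, ``Kp_t`` the tissue:plasma
partition coefficient and ``BP`` the blood:plasma ratio, so the emergent
venous blood leaves in equilibrium with the tissue.  Hepatic elimination is
first order on the liver outflow plasma concentration; a fixed molar
fraction of cleared parent forms 11-OH-THC in the liver.  Oral doses are
absorbed first order from a gut depot into the portal (liver) inflow —
giving first-pass extraction — inhaled doses first order from a lung depot
into the lung compartment, and IV doses enter venous blood as a bolus or a
constant-rate infusion.  All kinetics are linear in dose.

A degenerate one-compartment mode (``PKModelSpec.one_compartment``) routes
every dose into a single well-stirred compartment with first-order
elimination; it exists for analytic verification (the IV bolus solution is
``C(t) = D/V * exp(-CL/V * t)``) and for route-equivalence checks that the
full topology intentionally breaks via entry-site asymmetry.

Concentrations are carried in uM and amounts in umol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .params import CompoundParams, InvalidParameterError, dose_to_amount

Route = Literal["iv_bolus", "iv_infusion", "oral", "inhaled"]
ROUTES = ("iv_bolus", "iv_infusion", "oral", "inhaled")


class ConfigurationError(ValueError):
    """The model or dosing configuration is structurally invalid."""


class SolverError(RuntimeError):
    """The ODE solver failed or produced a non-physical state."""


@dataclass(frozen=True)
class DoseEvent:
    """One administration of the parent compound."""

    route: Route
    amount_mg: float
    start_time: float = 0.0  # h
    duration: float = 0.0  # h, > 0 only for iv_infusion

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ConfigurationError(f"unknown route {self.route!r}")
        if self.amount_mg < 0:
            raise ConfigurationError("dose amount must be >= 0")
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        if self.route == "iv_infusion" and self.amount_mg > 0 and self.duration <= 0:
            raise ConfigurationError("iv_infusion requires duration > 0")
        if self.route != "iv_infusion" and self.duration != 0:
            raise ConfigurationError("duration must be 0 for non-infusion routes")


@dataclass(frozen=True)
class Tissue:
    name: str
    volume: float  # L
    flow: float  # L/h of blood
    kp_parent: float  # tissue:plasma partition coefficient
    kp_metabolite: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.flow <= 0:
            raise InvalidParameterError(f"{self.name}: volume and flow must be > 0")
        if self.kp_parent <= 0 or self.kp_metabolite <= 0:
            raise InvalidParameterError(f"{self.name}: Kp must be > 0")


@dataclass(frozen=True)
class PKModelSpec:
    """Structural and physiological parameters of the PK engine.

    The shipped :func:`default_pk_fixture` is a desk-scale stand-in tuned
    only to coarse, publicly stated properties of THC disposition
    (brain:plasma ratio 2-5, low oral availability, fast inhaled uptake);
    it is **not** an authoritative parameterization.
    """

    kind: Literal["pbpk", "one_compartment"] = "pbpk"
    # --- pbpk topology ---
    v_venous: float = 3.5  # L
    v_arterial: float = 1.5  # L
    lung_volume: float = 0.5  # L
    lung_kp_parent: float = 1.0
    lung_kp_metabolite: float = 1.0
    cardiac_output: float = 390.0  # L/h
    tissues: tuple[Tissue, ...] = ()
    clearance_parent: float = 1.0  # L/h, on liver outflow plasma conc
    fraction_metabolized: float = 0.0  # of cleared parent forming metabolite
    clearance_metabolite: float = 1.0  # L/h
    bp_parent: float = 1.0  # blood:plasma ratio
    bp_metabolite: float = 1.0
    oral_target: Literal["portal", "venous"] = "portal"
    # --- one-compartment degenerate mode ---
    v_central: float = 1.0  # L

    def __post_init__(self) -> None:
        if self.clearance_parent <= 0 or self.clearance_metabolite <= 0:
            raise InvalidParameterError("clearances must be > 0")
        if not (0.0 <= self.fraction_metabolized <= 1.0):
            raise InvalidParameterError("fraction_metabolized must lie in [0, 1]")
        if self.kind == "one_compartment":
            if self.v_central <= 0:
                raise InvalidParameterError("v_central must be > 0")
            return
        if min(self.v_venous, self.v_arterial, self.lung_volume) <= 0:
            raise InvalidParameterError("blood/lung volumes must be > 0")
        if self.cardiac_output <= 0:
            raise InvalidParameterError("cardiac_output must be > 0")
        if self.bp_parent <= 0 or self.bp_metabolite <= 0:
            raise InvalidParameterError("blood:plasma ratios must be > 0")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate tissue names")
        for required in ("brain", "liver"):
            if required not in names:
                raise ConfigurationError(f"pbpk spec requires a {required!r} tissue")
        total_flow = sum(t.flow for t in self.tissues)
        if abs(total_flow - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ConfigurationError(
                f"tissue flows sum to {total_flow} L/h but cardiac output is "
                f"{self.cardiac_output} L/h"
            )

    @staticmethod
    def one_compartment(volume: float, clearance: float,
                        fraction_metabolized: float = 0.0,
                        clearance_metabolite: float = 1.0) -> "PKModelSpec":
        return PKModelSpec(
            kind="one_compartment",
            v_central=volume,
            clearance_parent=clearance,
            fraction_metabolized=fraction_metabolized,
            clearance_metabolite=clearance_metabolite,
        )

    def tissue(self, name: str) -> Tissue:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)


def default_pk_fixture() -> PKModelSpec:
    """Desk-scale default THC / 11-OH-THC disposition fixture.

    Volumes and flows are round physiological values for a 70 kg adult
    (cardiac output 6.5 L/min); partition coefficients and clearances are
    chosen so that the simulated brain:total-plasma ratio settles in the
    2-5-fold range, oral availability is low (high first-pass extraction),
    and inhaled absorption peaks within minutes.  Non-authoritative — see
    the class docstring.
    """
    return PKModelSpec(
        kind="pbpk",
        v_venous=3.5,
        v_arterial=1.5,
        lung_volume=0.5,
        lung_kp_parent=1.0,
        lung_kp_metabolite=1.0,
        cardiac_output=390.0,
        tissues=(
            Tissue("brain", volume=1.45, flow=45.0, kp_parent=3.5, kp_metabolite=3.5),
            Tissue("liver", volume=1.8, flow=90.0, kp_parent=10.0, kp_metabolite=5.0),
            Tissue("rest", volume=62.0, flow=255.0, kp_parent=3.0, kp_metabolite=1.5),
        ),
        clearance_parent=300.0,
        fraction_metabolized=0.25,
        clearance_metabolite=200.0,
        bp_parent=1.0,
        bp_metabolite=1.0,
        oral_target="portal",
    )


@dataclass
class ConcSeries:
    """Concentration-time trajectories for parent and metabolite.

    ``plasma`` holds venous plasma concentrations (uM), ``brain`` total
    brain tissue concentrations (uM), keyed by compound name.
    """

    times: np.ndarray  # h
    plasma: dict[str, np.ndarray]
    brain: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        for d in (self.plasma, self.brain):
            for k, v in d.items():
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{k}: trajectory/grid shape mismatch")
                if not np.all(np.isfinite(v)) or np.any(v < 0):
                    raise ValueError(f"{k}: concentrations must be finite and >= 0")
                d[k] = v

    @property
    def compounds(self) -> list[str]:
        return list(self.plasma)

    def brain_sum(self) -> np.ndarray:
        """Summed brain concentration over compounds (uM)."""
        return np.sum([self.brain[c] for c in self.brain], axis=0)

    def brain_interpolators(self) -> dict[str, PchipInterpolator]:
        return {c: PchipInterpolator(self.times, self.brain[c]) for c in self.brain}

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_h, compound, compartment, conc_uM)."""
        rows = []
        for compartment, data in (("plasma", self.plasma), ("brain", self.brain)):
            for compound, conc in data.items():
                rows.append(pd.DataFrame({
                    "time_h": self.times,
                    "compound": compound,
                    "compartment": compartment,
                    "conc_uM": conc,
                }))
        return pd.concat(rows, ignore_index=True)


def absorption_rate(event: DoseEvent, compound: CompoundParams,
                    depot_amount: float, t: float) -> float:
    """Instantaneous input rate (umol/h) contributed by one dose event.

    First-order for oral (``k_a * depot``) and inhaled (``lung_k_a *
    depot``), constant ``dose/duration`` inside an infusion window, and
    zero for an IV bolus, which transfers its amount as an instantaneous
    state jump rather than a finite rate.  Always zero before
    ``start_time``.
    """
    if t < event.start_time:
        return 0.0
    if event.route == "oral":
        return compound.k_a * depot_amount
    if event.route == "inhaled":
        return compound.lung_k_a * depot_amount
    if event.route == "iv_infusion":
        amount = dose_to_amount(event.amount_mg, compound.molar_mass)
        if event.start_time <= t < event.start_time + event.duration:
            return amount / event.duration
        return 0.0
    if event.route == "iv_bolus":
        return 0.0
    raise ConfigurationError(f"unknown route {event.route!r}")


# ---------------------------------------------------------------------------
# internal state layout and right-hand sides


class _Layout:
    """Index map for the flat ODE state vector."""

    def __init__(self, spec: PKModelSpec):
        self.spec = spec
        self.gut = 0
        self.lung_depot = 1
        if spec.kind == "one_compartment":
            self.p0 = 2          # parent central conc
            self.clr_p = 3
            self.m0 = 4          # metabolite central conc
            self.clr_m = 5
            self.n = 6
        else:
            nt = len(spec.tissues)
            self.p0 = 2          # parent concs: ven, art, lung, tissues...
            self.clr_p = self.p0 + 3 + nt
            self.m0 = self.clr_p + 1
            self.clr_m = self.m0 + 3 + nt
            self.n = self.clr_m + 1
            self.tissue_index = {t.name: i for i, t in enumerate(spec.tissues)}

    def conc_slice(self, base: int) -> slice:
        nt = len(self.spec.tissues)
        return slice(base, base + 3 + nt)


def _rhs_pbpk(spec: PKModelSpec, lay: _Layout, compound: CompoundParams):
    ts = spec.tissues
    q = np.array([t.flow for t in ts])
    v = np.array([t.volume for t in ts])
    kp_p = np.array([t.kp_parent for t in ts])
    kp_m = np.array([t.kp_metabolite for t in ts])
    i_liver = lay.tissue_index["liver"]
    co = spec.cardiac_output
    bp_p, bp_m = spec.bp_parent, spec.bp_metabolite

    def rhs(t, y, iv_rate):
        dy = np.zeros_like(y)
        r_oral = compound.k_a * y[lay.gut]
        r_inh = compound.lung_k_a * y[lay.lung_depot]
        dy[lay.gut] = -r_oral
        dy[lay.lung_depot] = -r_inh

        for (base, clr, kp, bp, cl) in (
            (lay.p0, lay.clr_p, kp_p, bp_p, spec.clearance_parent),
            (lay.m0, lay.clr_m, kp_m, bp_m, spec.clearance_metabolite),
        ):
            parent = base == lay.p0
            c_ven, c_art, c_lung = y[base], y[base + 1], y[base + 2]
            c_t = y[base + 3:base + 3 + len(ts)]
            out_t = c_t * bp / kp                 # emergent venous blood conc
            lung_kp = spec.lung_kp_parent if parent else spec.lung_kp_metabolite
            lung_out = c_lung * bp / lung_kp
            liver_plasma = c_t[i_liver] / kp[i_liver]
            elim = cl * liver_plasma

            d_ven = q @ out_t - co * c_ven
            d_lung = co * (c_ven - lung_out)
            d_art = co * (lung_out - c_art)
            d_t = q * (c_art - out_t)
            d_t[i_liver] -= elim
            if parent:
                d_ven += iv_rate
                d_lung += r_inh
                if spec.oral_target == "portal":
                    d_t[i_liver] += r_oral
                else:
                    d_ven += r_oral
            else:
                d_t[i_liver] += (
                    spec.fraction_metabolized * spec.clearance_parent
                    * y[lay.p0 + 3 + i_liver] / kp_p[i_liver]
                )
            dy[base] = d_ven / spec.v_venous
            dy[base + 1] = d_art / spec.v_arterial
            dy[base + 2] = d_lung / spec.lung_volume
            dy[base + 3:base + 3 + len(ts)] = d_t / v
            dy[clr] = elim
        return dy

    return rhs


def _rhs_one_compartment(spec: PKModelSpec, lay: _Layout, compound: CompoundParams):
    v = spec.v_central
    cl_p, cl_m = spec.clearance_parent, spec.clearance_metabolite
    fm = spec.fraction_metabolized

    def rhs(t, y, iv_rate):
        dy = np.zeros_like(y)
        r_oral = compound.k_a * y[lay.gut]
        r_inh = compound.lung_k_a * y[lay.lung_depot]
        dy[lay.gut] = -r_oral
        dy[lay.lung_depot] = -r_inh
        elim_p = cl_p * y[lay.p0]
        elim_m = cl_m * y[lay.m0]
        dy[lay.p0] = (iv_rate + r_oral + r_inh - elim_p) / v
        dy[lay.clr_p] = elim_p
        dy[lay.m0] = (fm * elim_p - elim_m) / v
        dy[lay.clr_m] = elim_m
        return dy

    return rhs


def _segments(regimen: Sequence[DoseEvent], t0: float, t_end: float):
    """Breakpoints at dose starts and infusion ends, within [t0, t_end]."""
    pts = {t0, t_end}
    for ev in regimen:
        if t0 <= ev.start_time <= t_end:
            pts.add(ev.start_time)
        stop = ev.start_time + ev.duration
        if ev.route == "iv_infusion" and t0 < stop < t_end:
            pts.add(stop)
    return sorted(pts)


@dataclass
class PKSolution:
    """Full engine state on the output grid, for diagnostics.

    ``administered_parent`` counts parent dose reaching depots or blood
    (f_a- or lung-f_a-scaled for extravascular routes) up to each time;
    amounts are umol summed over every compartment.
    """

    times: np.ndarray
    depot_gut: np.ndarray
    depot_lung: np.ndarray
    cleared_parent: np.ndarray
    cleared_metabolite: np.ndarray
    amount_parent: np.ndarray
    amount_metabolite: np.ndarray
    administered_parent: np.ndarray
    fraction_metabolized: float = 0.0

    def mass_balance_error(self) -> float:
        """Worst relative mass-balance defect over the grid, both compounds.

        Parent: administered = depots + in system + cleared.  Metabolite:
        molar amount formed (fm x parent cleared) = in system + cleared.
        Defects are relative to the administered / formed amount.
        """
        dose = self.administered_parent
        scale_p = np.maximum(dose, 1e-12)
        err_p = np.abs(
            dose - (self.depot_gut + self.depot_lung
                    + self.amount_parent + self.cleared_parent)
        ) / scale_p
        formed = self.fraction_metabolized * self.cleared_parent
        scale_m = np.maximum(formed, np.maximum(1e-6 * scale_p, 1e-12))
        err_m = np.abs(formed - (self.amount_metabolite
                                 + self.cleared_metabolite)) / scale_m
        return float(max(err_p.max(), err_m.max()))


def simulate_pk(
    spec: PKModelSpec,
    compounds: tuple[CompoundParams, CompoundParams],
    regimen: Sequence[DoseEvent],
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    full_output: bool = False,
):
    """Simulate parent + metabolite disposition for one dosing regimen.

    Parameters
    ----------
    spec
        Model structure and physiology.
    compounds
        ``(parent, metabolite)`` constants; absorption constants are read
        from the parent.
    regimen
        Dose events for the parent compound.
    times
        Strictly increasing output grid (h); must start at or before the
        first dose.
    full_output
        Also return a :class:`PKSolution` with depots, cleared amounts and
        the mass-balance audit.

    Returns
    -------
    ConcSeries, or ``(ConcSeries, PKSolution)`` when ``full_output``.

    Raises
    ------
    SolverError
        On integrator failure, state more negative than the tolerance
        allows (never silently clipped), or a mass-balance defect beyond
        0.1%.
    """
    parent, metabolite = compounds
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid of >= 2 points")
    for ev in regimen:
        if ev.start_time < times[0]:
            raise ConfigurationError("dose event precedes the output grid")

    lay = _Layout(spec)
    rhs = (_rhs_one_compartment if spec.kind == "one_compartment"
           else _rhs_pbpk)(spec, lay, parent)

    # times[0] reports the pre-dose state even when a dose lands exactly there
    y = np.zeros(lay.n)
    ys = np.zeros((lay.n, times.size))
    admin = np.zeros(times.size)
    admin_total = 0.0

    breaks = _segments(regimen, times[0], times[-1])
    for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
        # instantaneous dose applications at the segment start
        for ev in regimen:
            if ev.start_time == seg_start and ev.amount_mg > 0:
                amount = dose_to_amount(ev.amount_mg, parent.molar_mass)
                if ev.route == "iv_bolus":
                    v0 = spec.v_central if spec.kind == "one_compartment" else spec.v_venous
                    y[lay.p0] += amount / v0
                    admin_total += amount
                elif ev.route == "oral":
                    y[lay.gut] += parent.f_a * amount
                    admin_total += parent.f_a * amount
                elif ev.route == "inhaled":
                    y[lay.lung_depot] += parent.lung_f_a * amount
                    admin_total += parent.lung_f_a * amount
        iv_rate = sum(
            absorption_rate(ev, parent, 0.0, 0.5 * (seg_start + seg_end))
            for ev in regimen if ev.route == "iv_infusion"
        )
        idx = np.nonzero((times > seg_start) & (times <= seg_end))[0]
        t_eval = np.unique(np.concatenate([times[idx], [seg_end]]))
        sol = solve_ivp(
            rhs, (seg_start, seg_end), y, method="LSODA",
            t_eval=t_eval, args=(iv_rate,), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SolverError(f"PK integration failed on [{seg_start}, {seg_end}]: "
                              f"{sol.message}")
        pos = np.searchsorted(sol.t, times[idx])
        ys[:, idx] = sol.y[:, pos]
        admin[idx] = admin_total + iv_rate * (times[idx] - seg_start)
        y = sol.y[:, -1]
        admin_total += iv_rate * (seg_end - seg_start)

    neg_tol = 100 * atol + 1e-12
    if ys.min() < -neg_tol:
        raise SolverError(f"negative state {ys.min():.3e} beyond tolerance")
    ys = np.clip(ys, 0.0, None)

    series, solution = _assemble(spec, lay, parent, metabolite, times, ys, admin)
    err = solution.mass_balance_error()
    if err > 1e-3:
        raise SolverError(f"mass-balance defect {err:.2e} exceeds 0.1%")
    return (series, solution) if full_output else series


def _assemble(spec, lay, parent, metabolite, times, ys, admin):
    if spec.kind == "one_compartment":
        c_p = ys[lay.p0]
        c_m = ys[lay.m0]
        plasma = {parent.name: c_p, metabolite.name: c_m}
        brain = {parent.name: c_p.copy(), metabolite.name: c_m.copy()}
        amount_p = c_p * spec.v_central
        amount_m = c_m * spec.v_central
    else:
        nt = len(spec.tissues)
        i_brain = lay.tissue_index["brain"]
        vols = np.array([spec.v_venous, spec.v_arterial, spec.lung_volume]
                        + [t.volume for t in spec.tissues])
        p = ys[lay.p0:lay.p0 + 3 + nt]
        m = ys[lay.m0:lay.m0 + 3 + nt]
        plasma = {parent.name: p[0] / spec.bp_parent,
                  metabolite.name: m[0] / spec.bp_metabolite}
        brain = {parent.name: p[3 + i_brain], metabolite.name: m[3 + i_brain]}
        amount_p = vols @ p
        amount_m = vols @ m
    series = ConcSeries(times=times, plasma=plasma, brain=brain)
    solution = PKSolution(
        times=times,
        depot_gut=ys[lay.gut],
        depot_lung=ys[lay.lung_depot],
        cleared_parent=ys[lay.clr_p],
        cleared_metabolite=ys[lay.clr_m],
        amount_parent=amount_p,
        amount_metabolite=amount_m,
        administered_parent=admin,
        fraction_metabolized=spec.fraction_metabolized,
    )
    return series, solution
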