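"""Direct effect-compartment Emax model for VAS "feeling high".

Two hypothetical effect compartments, one per compound, lag the brain
concentrations with first-order transfer:

    dC_e/dt = k_e0 (C_brain(t) - C_e),    C_e(0) = 0.

The VAS score is a sigmoid Emax (Hill) transform of the *summed*
effect-site concentrations — THC and 11-OH-THC are assumed equipotent, so
the two compounds share one Emax and one EC50 and enter only through
their sum:

    score = E_max * S^h / (EC50^h + S^h),    S = C_THC,e + C_11OH,e.

The response is bounded by E_max (80 mm at the default parameters) and the
baseline is 0 mm: drug-naive subjects report no high.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from ._ode import integrate_linear_decay, refine_grid
from .params import FeelingHighParams
from .pk import ConcSeries
from .series import VASSeries

#: default refinement of the PD integration grid (h)
PD_MAX_STEP = 0.01


def simulate_effect_site(
    k_e0: float,
    brain_conc: Callable[[float], float] | np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Effect-site concentration driven by a brain concentration history.

    ``brain_conc`` may be a callable of time (integrated with a
    tightly-toleranced adaptive solver, for analytic forcing) or an array
    of values on ``times`` (integrated exactly under piecewise-linear
    forcing).  The effect site starts empty, matching a zero pre-dose
    brain concentration.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid")
    if k_e0 <= 0:
        raise ValueError("k_e0 must be > 0")
    if callable(brain_conc):
        sol = solve_ivp(
            lambda t, y: k_e0 * (brain_conc(t) - y),
            (times[0], times[-1]), [0.0], t_eval=times,
            method="LSODA", rtol=1e-11, atol=1e-13,
        )
        if not sol.success:
            raise RuntimeError(f"effect-site integration failed: {sol.message}")
        return np.maximum(sol.y[0], 0.0)
    forcing = k_e0 * np.asarray(brain_conc, dtype=float)
    return np.maximum(integrate_linear_decay(times, forcing, k_e0), 0.0)


def feeling_high_score(
    c_thc_eff: np.ndarray | float,
    c_11oh_eff: np.ndarray | float,
    p: FeelingHighParams,
) -> np.ndarray | float:
    """VAS "feeling high" (mm) from the two effect-site concentrations.

    Symmetric in its two arguments (shared potency) and monotone
    nondecreasing in each; bounded in [0, e_max).
    """
    c1 = np.asarray(c_thc_eff, dtype=float)
    c2 = np.asarray(c_11oh_eff, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("effect-site concentrations must be >= 0")
    s = c1 + c2
    with np.errstate(divide="ignore"):
        num = np.power(s, p.hill)
    score = p.e_max * num / (p.ec50 ** p.hill + num)
    return float(score) if np.isscalar(c_thc_eff) and np.isscalar(c_11oh_eff) else score


def simulate_feeling_high(
    conc: ConcSeries,
    p: FeelingHighParams,
    max_step: float = PD_MAX_STEP,
) -> VASSeries:
    """Compose effect-site kinetics with the Hill response for one subject.

    The brain trajectories are interpolated (monotone cubic) onto a
    refined grid before the exact piecewise-linear effect-site update, and
    the score is reported on the concentration grid.
    """
    fine = refine_grid(conc.times, max_step)
    interp = conc.brain_interpolators()
    names = conc.compounds
    ke0 = {names[0]: p.k_e0_thc, names[1]: p.k_e0_11oh}
    eff = {
        name: simulate_effect_site(ke0[name], np.maximum(f(fine), 0.0), fine)
        for name, f in interp.items()
    }
    keep = np.searchsorted(fine, conc.times)
    score = feeling_high_score(eff[names[0]][keep], eff[names[1]][keep], p)
    return VASSeries(times=conc.times, vas=score, endpoint="feeling_high")


def effect_site_series(
    conc: ConcSeries,
    p: FeelingHighParams,
    max_step: float = PD_MAX_STEP,
) -> dict[str, np.ndarray]:
    """Effect-site trajectories (uM) per compound on the concentration grid."""
    fine = refine_grid(conc.times, max_step)
    keep = np.searchsorted(fine, conc.times)
    names = conc.compounds
    ke0 = {names[0]: p.k_e0_thc, names[1]: p.k_e0_11oh}
    return {
        name: simulate_effect_site(ke0[name], np.maximum(f(fine), 0.0), fine)[keep]
        for name, f in conc.brain_interpolators().items()
    }
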