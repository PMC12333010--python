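"""Indirect-response (turnover) model for VAS "alertness".

Alertness is maintained by zero-order production ``k_in`` and first-order
loss ``k_out``; before dosing the score sits at its steady state, so
``k_in = baseline * k_out`` and the trajectory starts at the baseline
(60 mm by default).  THC and 11-OH-THC inhibit the production term through
a sigmoid Emax function of their *summed total brain concentrations* —
deliberately with no effect compartment, the turnover itself supplies the
lag between exposure and response:

    dV/dt = k_in (1 - E(t)) - k_out V,
    E(t)  = E_max * S^h / (EC50^h + S^h),   S = C_THC,brain + C_11OH,brain,

with E_max a maximal inhibition *fraction* (0.90 at the default 90%).
The trajectory is confined to (baseline*(1-E_max), baseline] and relaxes
back to baseline as the brain concentrations wash out.
"""

from __future__ import annotations

import numpy as np

from ._ode import integrate_linear_decay, refine_grid
from .params import AlertnessParams
from .pk import ConcSeries
from .series import VASSeries

PD_MAX_STEP = 0.01


def inhibition_fraction(
    c_thc_brain: np.ndarray | float,
    c_11oh_brain: np.ndarray | float,
    p: AlertnessParams,
) -> np.ndarray | float:
    """Fractional inhibition of the alertness input in [0, e_max_fraction)."""
    c1 = np.asarray(c_thc_brain, dtype=float)
    c2 = np.asarray(c_11oh_brain, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("brain concentrations must be >= 0")
    s = c1 + c2
    num = np.power(s, p.hill)
    frac = p.e_max_fraction * num / (p.ec50 ** p.hill + num)
    return (float(frac)
            if np.isscalar(c_thc_brain) and np.isscalar(c_11oh_brain) else frac)


def simulate_alertness(
    conc: ConcSeries,
    p: AlertnessParams,
    max_step: float = PD_MAX_STEP,
) -> VASSeries:
    """Integrate the turnover model from its baseline steady state.

    The production term is evaluated on a refined grid and the linear ODE
    advanced with an exact exponential update, so a zero-concentration
    input holds the baseline to machine precision.
    """
    fine = refine_grid(conc.times, max_step)
    interp = conc.brain_interpolators()
    names = conc.compounds
    e = inhibition_fraction(
        np.maximum(interp[names[0]](fine), 0.0),
        np.maximum(interp[names[1]](fine), 0.0),
        p,
    )
    forcing = p.k_in * (1.0 - e)
    vas = integrate_linear_decay(fine, forcing, p.k_out, y0=p.baseline)
    keep = np.searchsorted(fine, conc.times)
    return VASSeries(times=conc.times, vas=vas[keep], endpoint="alertness")


def alertness_trough(series: VASSeries) -> tuple[float, float]:
    """Time and value of the minimum alertness score (earliest tie wins)."""
    if series.times.size == 0:
        raise ValueError("empty series")
    i = int(np.argmin(series.vas))
    return float(series.times[i]), float(series.vas[i])
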