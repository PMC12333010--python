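"""Exact exponential integrators for the linear PD differential equations.

Both PD state equations have the form

    dy/dt = u(t) - k * y,    k > 0,

with forcing ``u``: the effect compartment uses ``u = k_e0 * C_brain`` and
the alertness turnover model uses ``u = k_in * (1 - E(t))``.  When ``u`` is
piecewise linear on the integration grid the update

    y_{n+1} = y_n e^{-k h} + a (1 - e^{-k h}) + b (h - (1 - e^{-k h}) / k)

with ``u(t) = a + b (t - t_n)`` on the step is exact, so constant forcing is
integrated with no discretisation error at all and smooth forcing converges
at second order in the grid spacing.  The update is vectorised over an
arbitrary number of parallel trajectories (virtual subjects).
"""

from __future__ import annotations

import numpy as np


def integrate_linear_decay(
    times: np.ndarray,
    forcing: np.ndarray,
    k: float,
    y0: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Integrate ``dy/dt = u(t) - k*y`` with piecewise-linear forcing.

    Parameters
    ----------
    times
        Strictly increasing grid, shape ``(n_t,)``.
    forcing
        Forcing values on the grid.  Shape ``(n_t,)`` for a single
        trajectory or ``(n_traj, n_t)`` for a batch.
    k
        First-order loss rate constant (1/h), > 0.
    y0
        Initial value(s) at ``times[0]``.

    Returns
    -------
    Array of the same shape as ``forcing`` with the solution on the grid.
    """
    times = np.asarray(times, dtype=float)
    u = np.atleast_2d(np.asarray(forcing, dtype=float))
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D grid with at least one point")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if u.shape[-1] != times.size:
        raise ValueError("forcing and times have incompatible shapes")
    if k <= 0:
        raise ValueError("loss rate constant k must be > 0")

    y = np.empty_like(u)
    y[:, 0] = y0
    h = np.diff(times)
    decay = np.exp(-k * h)
    # step response of the constant and ramp components of the forcing
    const_w = (1.0 - decay) / k
    ramp_w = (h - const_w) / k
    slope = (u[:, 1:] - u[:, :-1]) / h
    for n in range(times.size - 1):
        y[:, n + 1] = (
            y[:, n] * decay[n]
            + u[:, n] * const_w[n]
            + slope[:, n] * ramp_w[n]
        )
    out = y if np.asarray(forcing).ndim == 2 else y[0]
    return out


def refine_grid(times: np.ndarray, max_step: float) -> np.ndarray:
    """Return ``times`` with extra points inserted so no step exceeds ``max_step``.

    The original points are preserved exactly (so solutions can be read off
    at the requested grid without interpolation).
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return times.copy()
    pieces = [times[:1]]
    for a, b in zip(times[:-1], times[1:]):
        n = int(np.ceil((b - a) / max_step))
        pieces.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pieces)
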