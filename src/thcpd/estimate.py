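"""PD parameter estimation from observed mean VAS series.

Fits target the observed *mean* trajectory (the source data are digitized
mean curves), by bounded nonlinear least squares on the residuals between
the model-predicted and observed VAS at the observed times, given a
simulated brain-concentration input.  Positive scale-like parameters
(rates, Emax, EC50, Hill) are optimized in log space by default for
numerical conditioning; a seeded Latin-hypercube multi-start replaces the
manual optimization a GUI workflow would use, making the procedure
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from ._ode import integrate_linear_decay, refine_grid
from .params import AlertnessParams, FeelingHighParams
from .pk import ConcSeries
from .series import ObservedSeries

#: parameter names the fitter recognises, per endpoint
FREE_PARAMS = {
    "feeling_high": ("e_max", "ec50", "hill", "k_e0"),
    "alertness": ("e_max_pct", "ec50", "hill", "k_out"),
}

DEFAULT_BOUNDS = {
    "e_max": (1.0, 100.0),
    "e_max_pct": (1.0, 100.0),
    "ec50": (1e-3, 10.0),
    "hill": (0.5, 5.0),
    "k_e0": (0.05, 50.0),
    "k_out": (0.05, 50.0),
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names to (lower, upper) bounds; anything not
    listed stays at the value in ``base``.  ``log_scale`` parameters are
    searched on a log10 axis.  ``k_e0`` moves both compounds' transfer
    constants together (the published model shares one value).
    """

    endpoint: str
    free: dict[str, tuple[float, float]]
    base: FeelingHighParams | AlertnessParams = None  # population/init values
    log_scale: frozenset[str] = frozenset(
        {"e_max", "e_max_pct", "ec50", "hill", "k_e0", "k_out"})
    n_starts: int = 10
    seed: int = 0
    weights: np.ndarray | None = None  # optional per-point weights (e.g. n)

    def __post_init__(self) -> None:
        if self.endpoint not in FREE_PARAMS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        allowed = FREE_PARAMS[self.endpoint]
        for name in self.free:
            if name not in allowed:
                raise ValueError(f"{name!r} is not a free parameter of "
                                 f"{self.endpoint}: {allowed}")
        for name, (lo, hi) in self.free.items():
            if not (0 < lo < hi):
                raise ValueError(f"{name}: bounds must satisfy 0 < lo < hi")
        if self.base is None:
            base = (FeelingHighParams() if self.endpoint == "feeling_high"
                    else AlertnessParams())
            object.__setattr__(self, "base", base)


@dataclass
class FitResult:
    params: FeelingHighParams | AlertnessParams
    estimates: dict[str, float]
    loss: float  # sum of squared residuals at the optimum
    converged: bool
    residuals: np.ndarray
    n_starts: int
    seed: int


class _Predictor:
    """Precomputes the concentration forcing once; cheap per-theta evals."""

    def __init__(self, observed: ObservedSeries, conc: ConcSeries,
                 endpoint: str, max_step: float = 0.02):
        if (observed.times.min() < conc.times.min() - 1e-12
                or observed.times.max() > conc.times.max() + 1e-12):
            raise ValueError("observed times lie outside the concentration span")
        grid = np.unique(np.concatenate([conc.times, observed.times]))
        self.fine = refine_grid(grid, max_step)
        self.at_obs = np.searchsorted(self.fine, observed.times)
        interp = conc.brain_interpolators()
        names = conc.compounds
        self.b1 = np.maximum(interp[names[0]](self.fine), 0.0)
        self.b2 = np.maximum(interp[names[1]](self.fine), 0.0)
        self.endpoint = endpoint

    def __call__(self, p) -> np.ndarray:
        if self.endpoint == "feeling_high":
            e1 = integrate_linear_decay(self.fine, p.k_e0_thc * self.b1, p.k_e0_thc)
            e2 = integrate_linear_decay(self.fine, p.k_e0_11oh * self.b2, p.k_e0_11oh)
            s = np.maximum(e1 + e2, 0.0)[self.at_obs]
            num = np.power(s, p.hill)
            return p.e_max * num / (p.ec50 ** p.hill + num)
        s = self.b1 + self.b2
        num = np.power(s, p.hill)
        inhib = p.e_max_fraction * num / (p.ec50 ** p.hill + num)
        vas = integrate_linear_decay(
            self.fine, p.k_in * (1.0 - inhib), p.k_out, y0=p.baseline)
        return vas[self.at_obs]


def _apply(base, endpoint: str, names, values) -> FeelingHighParams | AlertnessParams:
    kw = dict(zip(names, values))
    if endpoint == "feeling_high" and "k_e0" in kw:
        ke0 = kw.pop("k_e0")
        kw["k_e0_thc"] = kw["k_e0_11oh"] = ke0
    return replace(base, **kw)


def fit_pd(observed: ObservedSeries, conc: ConcSeries, spec: FitSpec) -> FitResult:
    """Bounded multi-start least squares on the mean VAS trajectory.

    Returns the best start; if no start converges the result is flagged
    (``converged=False``) rather than raised.
    """
    names = list(spec.free)
    lo = np.array([spec.free[n][0] for n in names])
    hi = np.array([spec.free[n][1] for n in names])
    logmask = np.array([n in spec.log_scale for n in names])
    t_lo = np.where(logmask, np.log10(lo), lo)
    t_hi = np.where(logmask, np.log10(hi), hi)
    predict = _Predictor(observed, conc, spec.endpoint)
    target = observed.mean_vas
    w = np.ones_like(target) if spec.weights is None else np.sqrt(spec.weights)

    def residuals(theta):
        vals = np.where(logmask, 10.0 ** theta, theta)
        p = _apply(spec.base, spec.endpoint, names, vals)
        return w * (predict(p) - target)

    # start points: the population values plus a Latin-hypercube spread
    base_vals = []
    for n in names:
        v = getattr(spec.base, "k_e0_thc" if n == "k_e0" else n)
        base_vals.append(np.clip(v, spec.free[n][0], spec.free[n][1]))
    starts = [np.where(logmask, np.log10(base_vals), base_vals)]
    if spec.n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(spec.n_starts - 1)
        starts.extend(t_lo + unit * (t_hi - t_lo))

    best = None
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(t_lo, t_hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        loss = float(np.sum(sol.fun ** 2))
        any_converged = any_converged or sol.success
        if best is None or loss < best[0]:
            best = (loss, sol)
    if best is None:
        raise RuntimeError("all optimization starts failed to evaluate")
    loss, sol = best
    vals = np.where(logmask, 10.0 ** sol.x, sol.x)
    params = _apply(spec.base, spec.endpoint, names, vals)
    return FitResult(
        params=params,
        estimates=dict(zip(names, map(float, vals))),
        loss=loss,
        converged=any_converged,
        residuals=np.asarray(sol.fun, dtype=float) / w,
        n_starts=len(starts),
        seed=spec.seed,
    )


def profile_loss(
    observed: ObservedSeries,
    conc: ConcSeries,
    spec: FitSpec,
    parameter: str,
    grid: np.ndarray,
) -> np.ndarray:
    """Profile objective: loss on a fixed grid of one parameter, others refit.

    A flat valley over correlated parameter pairs (the classic Emax-EC50
    ridge on data that never approach saturation) shows up directly as a
    near-constant profile.
    """
    if parameter not in spec.free:
        raise ValueError(f"{parameter!r} is not free in this spec")
    lo, hi = spec.free[parameter]
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < lo) | (grid > hi)):
        raise ValueError("profile grid extends outside the parameter bounds")
    others = {n: b for n, b in spec.free.items() if n != parameter}
    losses = np.empty(grid.size)
    for i, value in enumerate(grid):
        base_i = _apply(spec.base, spec.endpoint, [parameter], [value])
        if others:
            sub = replace(spec, free=others, base=base_i,
                          n_starts=max(1, spec.n_starts // 2))
            losses[i] = fit_pd(observed, conc, sub).loss
        else:
            pred = _Predictor(observed, conc, spec.endpoint)(base_i)
            losses[i] = float(np.sum((pred - observed.mean_vas) ** 2))
    return losses
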