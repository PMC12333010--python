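"""Model-acceptance statistics against observed VAS series.

Prediction performance is judged the way PBPK-PD verifications are
reported: the ratio of predicted to observed extreme score (R_max — peaks
for feeling high, troughs for alertness), whether that ratio falls inside
a fold range (2-fold for feeling high, 1.3-fold for alertness, bounds
inclusive), and the fraction of observed points lying inside the
predicted 5th-95th percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import ObservedSeries, SummarySeries, VASSeries

FOLD_FEELING_HIGH = 2.0
FOLD_ALERTNESS = 1.3


class UndefinedRatioError(ZeroDivisionError):
    """The observed extreme is zero, so the fold ratio is undefined."""


def rmax_ratio(predicted_extreme: float, observed_extreme: float) -> float:
    """Ratio of predicted to observed extreme VAS score."""
    if observed_extreme == 0:
        raise UndefinedRatioError("observed extreme is zero")
    return predicted_extreme / observed_extreme


def fold_check(ratio: float, fold: float) -> bool:
    """True iff ``1/fold <= ratio <= fold`` (inclusive bounds)."""
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return 1.0 / fold <= ratio <= fold


def observed_extreme(observed: ObservedSeries) -> float:
    """Extreme of the observed mean curve on its own grid (no smoothing)."""
    if observed.endpoint == "alertness":
        return float(observed.mean_vas.min())
    return float(observed.mean_vas.max())


def predicted_extreme(series: VASSeries | SummarySeries,
                      endpoint: str | None = None) -> float:
    """Extreme of a predicted trajectory: peak (feeling high) or trough."""
    values = series.vas if isinstance(series, VASSeries) else series.mean
    if endpoint is None and isinstance(series, VASSeries):
        endpoint = series.endpoint
    if endpoint is None:
        raise ValueError("endpoint required for a summary series")
    if endpoint == "alertness":
        return float(values.min())
    return float(values.max())


def percentile_coverage(observed: ObservedSeries, summary: SummarySeries) -> float:
    """Fraction of observed points inside the predicted [p5, p95] band.

    Band edges are linearly interpolated to the observed times; observed
    times outside the summary span are an error (no extrapolation).
    """
    t = observed.times
    if t.min() < summary.times.min() - 1e-12 or t.max() > summary.times.max() + 1e-12:
        raise ValueError("observed times extend beyond the summary span")
    lo = np.interp(t, summary.times, summary.p5)
    hi = np.interp(t, summary.times, summary.p95)
    inside = (observed.mean_vas >= lo - 1e-12) & (observed.mean_vas <= hi + 1e-12)
    return float(inside.mean())


@dataclass
class TrialVerification:
    trial: str
    endpoint: str
    r_max: float
    fold: float
    fold_pass: bool
    coverage: float


@dataclass
class VerificationReport:
    """Per-trial ratios and the aggregate pass statistics."""

    trials: list[TrialVerification]

    @property
    def pass_rate(self) -> float:
        if not self.trials:
            raise ValueError("empty report")
        return float(np.mean([t.fold_pass for t in self.trials]))

    @property
    def mean_coverage(self) -> float:
        return float(np.mean([t.coverage for t in self.trials]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])

    def summary_text(self) -> str:
        lines = [
            f"{len(self.trials)} trial(s) verified",
            f"fold-range pass rate: {100 * self.pass_rate:.0f}%",
            f"mean percentile coverage: {100 * self.mean_coverage:.0f}%",
        ]
        for t in self.trials:
            lines.append(
                f"  {t.trial or '<unnamed>'} [{t.endpoint}] "
                f"R_max={t.r_max:.2f} ({'pass' if t.fold_pass else 'FAIL'} "
                f"at {t.fold}-fold), coverage={100 * t.coverage:.0f}%"
            )
        return "\n".join(lines)


def verify_trial(
    observed: ObservedSeries,
    summary: SummarySeries,
    fold: float | None = None,
) -> TrialVerification:
    """Verify one observed series against one simulated summary."""
    if fold is None:
        fold = FOLD_ALERTNESS if observed.endpoint == "alertness" else FOLD_FEELING_HIGH
    pred = (float(summary.mean.min()) if observed.endpoint == "alertness"
            else float(summary.mean.max()))
    r = rmax_ratio(pred, observed_extreme(observed))
    return TrialVerification(
        trial=observed.trial,
        endpoint=observed.endpoint,
        r_max=r,
        fold=fold,
        fold_pass=fold_check(r, fold),
        coverage=percentile_coverage(observed, summary),
    )


def verify_batch(
    pairs: list[tuple[ObservedSeries, SummarySeries]],
    fold: float | None = None,
) -> VerificationReport:
    return VerificationReport([verify_trial(o, s, fold) for o, s in pairs])
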