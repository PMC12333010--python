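"""Shared time-series containers for VAS trajectories and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def clip_vas(values: np.ndarray) -> np.ndarray:
    """Clip VAS scores to the physical 0-100 mm scale.

    Applied only at reporting boundaries; the models themselves are
    naturally bounded and are never clipped internally.
    """
    return np.clip(values, 0.0, 100.0)


@dataclass
class VASSeries:
    """A single VAS trajectory (mm) on a time grid (h)."""

    times: np.ndarray
    vas: np.ndarray
    endpoint: str = "feeling_high"  # or "alertness"
    subject_id: int | None = None
    trial_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vas = np.asarray(self.vas, dtype=float)
        if self.times.shape != self.vas.shape or self.times.ndim != 1:
            raise ValueError("times and vas must be matching 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "subject_id": -1 if self.subject_id is None else self.subject_id,
            "trial_id": -1 if self.trial_id is None else self.trial_id,
            "endpoint": self.endpoint,
            "vas_mm": clip_vas(self.vas),
        })


@dataclass
class SummarySeries:
    """Population summary of VAS trajectories: mean and 5th-95th percentiles."""

    times: np.ndarray
    mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    n: int

    def __post_init__(self) -> None:
        for name in ("times", "mean", "p5", "p95"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.times.shape == self.mean.shape == self.p5.shape == self.p95.shape):
            raise ValueError("summary components must share one grid")
        if np.any(self.p5 > self.p95 + 1e-12):
            raise ValueError("p5 must not exceed p95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "mean_vas_mm": self.mean,
            "p5_vas_mm": self.p5,
            "p95_vas_mm": self.p95,
            "n": self.n,
        })


@dataclass
class ObservedSeries:
    """An observed (or synthetic-observed) mean VAS trajectory.

    Mirrors the structure of digitized literature curves: mean score over
    subjects at clinical sampling times, optionally with an SD and the
    contributing n.
    """

    times: np.ndarray
    mean_vas: np.ndarray
    sd: np.ndarray | None = None
    n: int | None = None
    endpoint: str = "feeling_high"
    trial: str = ""
    dose_mg: float | None = None
    route: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_vas = np.asarray(self.mean_vas, dtype=float)
        if self.times.shape != self.mean_vas.shape or self.times.ndim != 1:
            raise ValueError("times and mean_vas must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.mean_vas < 0) | (self.mean_vas > 100)):
            raise ValueError("VAS must lie in [0, 100] mm")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape or np.any(self.sd < 0):
                raise ValueError("sd must be non-negative and match the grid")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.times, "vas_mm": self.mean_vas})
        if self.sd is not None:
            out["sd_mm"] = self.sd
        if self.n is not None:
            out["n"] = self.n
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "ObservedSeries":
        return cls(
            times=df["time_h"].to_numpy(),
            mean_vas=df["vas_mm"].to_numpy(),
            sd=df["sd_mm"].to_numpy() if "sd_mm" in df else None,
            n=int(df["n"].iloc[0]) if "n" in df else None,
            **meta,
        )
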