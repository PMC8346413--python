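"""Model-validation machinery: RMSD, the SD validity rule, band counting.

Predictions are compared against observed temperature series (group mean
with a standard deviation) on a common 10-min grid.  A prediction is
considered valid when the root-mean-square deviation does not exceed the
observed SD; a predicted endpoint is "within band" when it falls inside
measured mean +/- SD (both conventions closed at the boundary).

Because raw human time-series are rarely publishable, a synthetic
observed-series generator is included: it corrupts a known truth trajectory
with independent Gaussian subject noise and reports the across-subject mean
and SD, which makes the whole comparison pipeline testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Comparison grid spacing, minutes.
COMPARISON_INTERVAL_MIN = 10.0


@dataclass(frozen=True)
class ObservedSeries:
    """Observed group mean (+SD) of one variable over time."""

    times: np.ndarray    # min
    mean: np.ndarray     # C
    sd: np.ndarray       # C (per time point)
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mean, dtype=float)
        s = np.broadcast_to(np.asarray(self.sd, dtype=float), m.shape).copy()
        if t.size == 0:
            raise InputError("observed series is empty")
        if t.size != m.size:
            raise InputError("times and mean differ in length")
        if np.any(s < 0):
            raise InputError("observed SD must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ObservedSeries":
        frame = pd.read_csv(path)
        for col in ("time_min", "mean", "sd"):
            if col not in frame.columns:
                raise InputError(f"{path}: observed-series CSV missing column {col!r}")
        return cls(times=frame["time_min"].to_numpy(),
                   mean=frame["mean"].to_numpy(),
                   sd=frame["sd"].to_numpy(), label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times, "mean": self.mean,
                      "sd": self.sd}).to_csv(path, index=False)

    @property
    def mean_sd(self) -> float:
        """Time-averaged observed SD (the validity yardstick)."""
        return float(np.mean(self.sd))


@dataclass(frozen=True)
class ComparisonStats:
    rmsd: float
    observed_sd: float
    valid: bool
    n_points: int


def resample(times: Sequence[float], values: Sequence[float],
             grid: Sequence[float]) -> np.ndarray:
    """Linear interpolation of a series onto a comparison grid."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if g.min() < t.min() - 1e-9 or g.max() > t.max() + 1e-9:
        raise InputError("comparison grid extends beyond the series")
    return np.interp(g, t, v)


def comparison_grid(t_start: float, t_end: float,
                    interval: float = COMPARISON_INTERVAL_MIN) -> np.ndarray:
    return np.arange(t_start, t_end + 1e-9, interval)


def rmsd(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square deviation between two equal-length series, C."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise InputError(
            f"observed ({obs.size}) and predicted ({pred.size}) lengths differ")
    if obs.size == 0:
        raise InputError("cannot compute RMSD of empty series")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def validity(observed: ObservedSeries, predicted_times: Sequence[float],
             predicted_values: Sequence[float],
             interval: float = COMPARISON_INTERVAL_MIN) -> ComparisonStats:
    """RMSD on the 10-min comparison grid and the SD validity verdict."""
    grid = comparison_grid(observed.times.min(), observed.times.max(), interval)
    obs = resample(observed.times, observed.mean, grid)
    pred = resample(predicted_times, predicted_values, grid)
    value = rmsd(obs, pred)
    sd = float(np.mean(resample(observed.times, observed.sd, grid)))
    return ComparisonStats(rmsd=value, observed_sd=sd,
                           valid=value <= sd, n_points=grid.size)


def validity_from_stats(rmsd_value: float, observed_sd: float,
                        n_points: int = 0) -> ComparisonStats:
    """The SD rule applied to precomputed numbers (boundary counts as valid)."""
    if rmsd_value < 0 or observed_sd < 0:
        raise InputError("rmsd and sd must be >= 0")
    return ComparisonStats(rmsd=rmsd_value, observed_sd=observed_sd,
                           valid=rmsd_value <= observed_sd, n_points=n_points)


def within_band_count(endpoints: Sequence[tuple[float, float, float]]) -> int:
    """Count predictions inside measured mean +/- SD (closed band).

    ``endpoints`` are (measured_mean, measured_sd, predicted) triples.
    """
    count = 0
    for mean, sd, pred in endpoints:
        if not all(np.isfinite([mean, sd, pred])):
            raise InputError("endpoints must be finite")
        if abs(pred - mean) <= sd:
            count += 1
    return count


def synth_observed(times: Sequence[float], truth: Sequence[float], sd: float,
                   n_subjects: int, seed: int, label: str = "synthetic",
                   ) -> ObservedSeries:
    """Synthesize an observed group series from a known truth trajectory.

    Each of ``n_subjects`` subjects is the truth plus independent Gaussian
    noise with standard deviation ``sd`` at every time point; the returned
    series carries the across-subject mean and (ddof=1 when possible) SD.
    Deterministic for a fixed seed.
    """
    if sd < 0:
        raise InputError("sd must be >= 0")
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    t = np.asarray(times, dtype=float)
    base = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    subjects = base[None, :] + rng.normal(0.0, sd, size=(n_subjects, base.size))
    mean = subjects.mean(axis=0)
    spread = subjects.std(axis=0, ddof=1) if n_subjects > 1 else np.zeros_like(mean)
    return ObservedSeries(times=t, mean=mean, sd=spread, label=label)
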