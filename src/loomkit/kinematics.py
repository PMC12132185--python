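"""Speed traces from position tracks.

Positions are converted to scalar speed, resampled to a uniform 30 Hz grid
by linear interpolation, and smoothed with a 5-point centered moving
average (the window shrinks at the edges).  Two speed definitions are
exposed:

``euclidean`` (default)
    per-step speed = ||Δ(x, y)|| / Δt — true path speed, invariant under
    translation of the arena coordinates.

``paper_literal``
    per-step speed = |Δ sqrt(x² + y²)| / Δt — the change of radial distance
    from the arena origin.  This is origin-dependent and vanishes on
    circular paths around the origin; it is retained for replication of
    analyses that used it, not as a default.

Baseline referencing follows the assay's conventions: z-scores against the
mean/SD of a pre-stimulus window (10 s for heatmap-style normalisation,
5 s for per-trial speed-change figures), median speed over the 5 s before
onset ("pre-stimulus speed") or over the preceding 2.5 min ("foraging
speed").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import SessionRecording

__all__ = [
    "SpeedTrace",
    "ZScoreTrace",
    "DegenerateBaselineError",
    "speed_from_positions",
    "smooth_moving_average",
    "zscore_speed",
    "median_speed",
]

RESAMPLE_RATE_HZ = 30.0
SMOOTH_WINDOW = 5


class DegenerateBaselineError(ValueError):
    """Baseline SD is zero (frozen baseline) — z-scoring undefined."""


@dataclass
class SpeedTrace:
    """Uniformly sampled scalar speed in cm/s."""

    rate_hz: float
    t0_s: float
    values: np.ndarray
    mode: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    def window_slice(self, start_s: float, stop_s: float) -> slice:
        """Index slice of samples with start_s <= t < stop_s (half-open)."""
        t = self.times
        i0 = int(np.searchsorted(t, start_s - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, stop_s - 1e-12, side="left"))
        return slice(i0, i1)

    def window_values(self, start_s: float, stop_s: float) -> np.ndarray:
        return self.values[self.window_slice(start_s, stop_s)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "speed_cm_s": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


@dataclass
class ZScoreTrace:
    """Baseline-referenced dimensionless speed trace."""

    rate_hz: float
    t0_s: float
    values: np.ndarray
    baseline_window_s: float
    baseline_mean: float
    baseline_sd: float

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz


def speed_from_positions(
    rec: SessionRecording,
    mode: str = "euclidean",
    rate_hz: float = RESAMPLE_RATE_HZ,
    smooth_window: int = SMOOTH_WINDOW,
) -> SpeedTrace:
    """Instantaneous speed, resampled to ``rate_hz`` and smoothed.

    Per-step speeds are assigned to the midpoint of each frame pair, then
    linearly interpolated onto the uniform output grid.  Steps touching a
    missing (NaN) frame are dropped before interpolation, so gaps are
    bridged linearly in speed.
    """
    if mode not in ("euclidean", "paper_literal"):
        raise ValueError(f"unknown mode {mode!r}")
    t = rec.timestamps
    xy = rec.xy
    if len(t) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    dt = np.diff(t)
    if mode == "euclidean":
        step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    else:
        r = np.hypot(xy[:, 0], xy[:, 1])
        step = np.abs(np.diff(r))
    raw = step / dt
    tm = 0.5 * (t[:-1] + t[1:])
    good = np.isfinite(raw)
    if good.sum() < 2:
        raise ValueError("fewer than 2 finite speed samples")
    n_out = max(int(np.floor((tm[good][-1] - tm[good][0]) * rate_hz)) + 1, 1)
    grid = tm[good][0] + np.arange(n_out) / rate_hz
    resampled = np.interp(grid, tm[good], raw[good])
    smoothed = smooth_moving_average(resampled, smooth_window)
    return SpeedTrace(rate_hz=rate_hz, t0_s=float(grid[0]), values=smoothed, mode=mode)


def smooth_moving_average(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; the window shrinks near the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=window, center=True, min_periods=1).mean().to_numpy()


def zscore_speed(
    trace: SpeedTrace, stim_onset_s: float, baseline_window_s: float = 10.0
) -> ZScoreTrace:
    """Z-score the whole trace against the pre-onset baseline window.

    The baseline is the half-open window [onset − w, onset).  A frozen
    baseline (SD = 0) raises :class:`DegenerateBaselineError` rather than
    silently producing zeros.
    """
    base = trace.window_values(stim_onset_s - baseline_window_s, stim_onset_s)
    if len(base) == 0:
        raise ValueError("baseline window lies outside the trace")
    t = trace.times
    if stim_onset_s - baseline_window_s < t[0] - 0.5 / trace.rate_hz:
        raise ValueError("baseline window starts before the trace")
    mu = float(np.mean(base))
    sd = float(np.std(base))
    if sd <= 0:
        raise DegenerateBaselineError(
            f"baseline SD is zero over [{stim_onset_s - baseline_window_s}, {stim_onset_s}) s"
        )
    return ZScoreTrace(
        rate_hz=trace.rate_hz,
        t0_s=trace.t0_s,
        values=(trace.values - mu) / sd,
        baseline_window_s=baseline_window_s,
        baseline_mean=mu,
        baseline_sd=sd,
    )


def median_speed(trace: SpeedTrace, onset_s: float, window_s: float) -> float:
    """Median speed over the half-open window [onset − w, onset).

    With ``window_s=5`` this is the pre-stimulus speed; with 150 s the
    foraging speed.
    """
    vals = trace.window_values(onset_s - window_s, onset_s)
    if len(vals) == 0:
        raise ValueError("empty median window")
    return float(np.median(vals))
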