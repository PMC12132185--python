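"""Diagnostic plots: trajectories, speed traces, spectra, correlograms.

These are thin matplotlib helpers for quick visual inspection; they return
the Axes so callers can compose figures.
"""

from __future__ import annotations

import numpy as np
from matplotlib import patches as mpatches

from .arena import SessionRecording, StimulusSchedule, ZoneSet
from .kinematics import SpeedTrace
from .rhythm import PowerSpectrum

__all__ = ["plot_trajectory", "plot_speed_trace", "plot_spectrum", "plot_correlogram"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(rec: SessionRecording, zones: ZoneSet | None = None, ax=None):
    """Top-down path through the arena, colored by time."""
    ax = _ax(ax)
    if zones is not None:
        for z in zones.as_dict().values():
            ax.add_patch(
                mpatches.Rectangle(
                    (z.x_lo, z.y_lo), z.x_hi - z.x_lo, z.y_hi - z.y_lo,
                    fill=False, linewidth=0.5, edgecolor="gray",
                )
            )
    pts = ax.scatter(rec.xy[:, 0], rec.xy[:, 1], c=rec.timestamps, s=2, cmap="viridis")
    ax.scatter(*rec.arena.shelter_xy.T, marker="^", color="red", label="shelter")
    ax.set_xlim(0, rec.arena.length_cm)
    ax.set_ylim(0, rec.arena.width_cm)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    ax.figure.colorbar(pts, ax=ax, label="time (s)")
    return ax


def plot_speed_trace(trace: SpeedTrace, schedule: StimulusSchedule | None = None, ax=None):
    """Speed over time with stimulus onsets ticked."""
    ax = _ax(ax)
    ax.plot(trace.times, trace.values, lw=0.8)
    if schedule is not None:
        for o in schedule.onsets_s:
            ax.axvline(o, color="orange", lw=0.5, alpha=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("speed (cm/s)")
    return ax


def plot_spectrum(spec: PowerSpectrum, ax=None, max_freq_hz: float = 5.0):
    ax = _ax(ax)
    sel = spec.freqs_hz <= max_freq_hz
    ax.plot(spec.freqs_hz[sel], spec.power[sel])
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (cm/s)$^2$")
    return ax


def plot_correlogram(lags_s: np.ndarray, r: np.ndarray, ax=None, max_lag_s: float = 10.0):
    ax = _ax(ax)
    sel = np.abs(lags_s) <= max_lag_s
    ax.plot(lags_s[sel], r[sel])
    ax.axvline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("r")
    return ax
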