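"""Threshold-based event extraction from speed traces and position tracks.

All thresholds follow the assay conventions and use strict inequalities:
running is speed > 30 cm/s sustained for at least 3 consecutive frames
(the 97.5th percentile of Mus baseline speeds), stillness is speed
< 5 cm/s, shelter entry is distance < 5 cm from a shelter corner, and a
cricket approach is distance < 10 cm sustained for at least 10 frames.
Frame-count thresholds are applied on the 30 Hz resampled grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .arena import SessionRecording, StimulusSchedule, ZoneSet
from .kinematics import SpeedTrace

__all__ = [
    "RunningBout",
    "ApproachStats",
    "ShelterMetrics",
    "TrialFeatures",
    "detect_bouts",
    "baseline_threshold",
    "latency_to_running",
    "max_speed_window",
    "stopping_time",
    "shelter_metrics",
    "zone_occupancy",
    "detect_approaches",
    "ends_in_safety",
    "extract_trial_features",
]

RUN_THRESHOLD_CM_S = 30.0
RUN_MIN_FRAMES = 3
STILL_THRESHOLD_CM_S = 5.0
SHELTER_ENTRY_RADIUS_CM = 5.0
APPROACH_DIST_CM = 10.0
APPROACH_MIN_FRAMES = 10


@dataclass(frozen=True)
class RunningBout:
    """A maximal run of consecutive samples above the running threshold.

    ``end_s`` is exclusive (start_s + n_frames / rate), so bout durations
    tile the trace together with the gaps between them.
    """

    start_s: float
    end_s: float
    peak_speed: float
    n_frames: int


@dataclass(frozen=True)
class ApproachStats:
    n: int
    latency_s: float | None
    total_duration_s: float


@dataclass(frozen=True)
class ShelterMetrics:
    latency_shelter_s: float | None
    n_entries: int
    frac_time_in_shelter: float
    distance_trace: np.ndarray


@dataclass
class TrialFeatures:
    """Per-trial scalar descriptors of a single stimulus presentation.

    Latency fields are ``None`` (not 0) when the event never occurs.
    """

    latency_run_s: float | None = None
    n_bouts: int = 0
    max_speed_5s: float = 0.0
    stopping_time_s: float = 0.0
    latency_shelter_s: float | None = None
    n_shelter_entries: int = 0
    frac_time_in_shelter: float = 0.0
    pre_stim_median_speed: float = 0.0
    pct_time_danger: float = 0.0
    pct_time_center: float = 0.0
    pct_time_shelter: float = 0.0
    ends_in_safety: bool = False
    n_approaches: int = 0
    approach_latency_s: float | None = None
    approach_total_s: float = 0.0

    def to_row(self) -> dict:
        return asdict(self)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index runs of True in a boolean mask."""
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_bouts(
    trace: SpeedTrace,
    threshold: float = RUN_THRESHOLD_CM_S,
    min_frames: int = RUN_MIN_FRAMES,
) -> list[RunningBout]:
    """Maximal runs of consecutive samples strictly above ``threshold``.

    Runs shorter than ``min_frames`` are discarded.  Bouts are returned in
    time order and never overlap.
    """
    mask = trace.values > threshold
    t = trace.times
    dt = 1.0 / trace.rate_hz
    bouts = []
    for lo, hi in _runs(mask):
        if hi - lo >= min_frames:
            bouts.append(
                RunningBout(
                    start_s=float(t[lo]),
                    end_s=float(t[lo] + (hi - lo) * dt),
                    peak_speed=float(trace.values[lo:hi].max()),
                    n_frames=hi - lo,
                )
            )
    return bouts


def baseline_threshold(speeds: np.ndarray, q: float = 97.5) -> float:
    """Empirical percentile of pooled baseline speeds (linear interpolation).

    With the default q this reproduces the derivation of the 30 cm/s
    running threshold from baseline speed pools.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("empty baseline speed pool")
    return float(np.percentile(speeds, q, method="linear"))


def latency_to_running(
    bouts: list[RunningBout], stim_onset_s: float, tol_s: float = 0.0
) -> float | None:
    """Time from stimulus onset to the first bout starting at or after it.

    ``tol_s`` admits bouts starting up to that long *before* the onset:
    the centered 5-point smoothing can advance a measured bout onset by up
    to two frames, so trial-level extraction uses a small tolerance
    (latencies may then be slightly negative).
    """
    for b in bouts:
        if b.start_s >= stim_onset_s - tol_s - 1e-9:
            return float(b.start_s - stim_onset_s)
    return None


def max_speed_window(trace: SpeedTrace, stim_onset_s: float, window_s: float = 5.0) -> float:
    """Maximal speed in the first ``window_s`` seconds after stimulus onset."""
    vals = trace.window_values(stim_onset_s, stim_onset_s + window_s)
    if len(vals) == 0:
        raise ValueError("empty max-speed window")
    return float(vals.max())


def stopping_time(
    trace: SpeedTrace,
    window_start_s: float,
    window_stop_s: float,
    still_threshold: float = STILL_THRESHOLD_CM_S,
) -> float:
    """Longest run of samples strictly below ``still_threshold`` in the window, in s."""
    vals = trace.window_values(window_start_s, window_stop_s)
    runs = _runs(vals < still_threshold)
    longest = max((hi - lo for lo, hi in runs), default=0)
    return longest / trace.rate_hz


def shelter_metrics(
    rec: SessionRecording,
    window_start_s: float,
    window_stop_s: float,
    entry_radius_cm: float = SHELTER_ENTRY_RADIUS_CM,
) -> ShelterMetrics:
    """Shelter entry latency/count/occupancy from distance to shelter corners.

    "Inside" means distance < ``entry_radius_cm`` to the nearest shelter
    corner (the assay's definition, robust to small shelter movements).
    An animal already inside at the window start counts as one entry with
    zero latency.  NaN frames count as outside and are excluded from the
    occupancy denominator.
    """
    t = rec.timestamps
    sel = (t >= window_start_s - 1e-12) & (t < window_stop_s - 1e-12)
    xy = rec.xy[sel]
    tw = t[sel]
    corners = rec.arena.shelter_xy
    if len(xy) == 0:
        return ShelterMetrics(None, 0, 0.0, np.empty(0))
    diff = xy[:, None, :] - corners[None, :, :]
    dist = np.nanmin(np.linalg.norm(diff, axis=2), axis=1) if len(corners) else np.full(len(xy), np.nan)
    with np.errstate(invalid="ignore"):
        inside = dist < entry_radius_cm
    inside = np.where(np.isfinite(dist), inside, False)
    valid = np.isfinite(dist)
    entries = _runs(inside)
    n_entries = len(entries)
    latency = float(tw[entries[0][0]] - window_start_s) if entries else None
    frac = float(inside.sum() / valid.sum()) if valid.any() else 0.0
    return ShelterMetrics(latency, n_entries, frac, dist)


def zone_occupancy(
    rec: SessionRecording,
    zones: ZoneSet,
    window_start_s: float,
    window_stop_s: float,
) -> dict[str, float]:
    """Percent of window frames spent in each zone (zones judged independently).

    Membership is half-open ([lo, hi) on each axis).  NaN frames are
    excluded from the denominator.
    """
    t = rec.timestamps
    sel = (t >= window_start_s - 1e-12) & (t < window_stop_s - 1e-12)
    xy = rec.xy[sel]
    valid = np.isfinite(xy).all(axis=1)
    n_valid = int(valid.sum())
    out = {}
    for name, zone in zones.as_dict().items():
        if n_valid == 0:
            out[name] = float("nan")
        else:
            out[name] = float(zone.contains(xy[valid]).sum() / n_valid * 100.0)
    return out


def detect_approaches(
    rec: SessionRecording,
    target_track: np.ndarray,
    max_dist_cm: float = APPROACH_DIST_CM,
    min_frames: int = APPROACH_MIN_FRAMES,
    target_y_cm: float = 0.0,
) -> ApproachStats:
    """Approaches to a moving target (e.g. the virtual cricket).

    ``target_track`` is an (m, 2) array of (time_s, position_cm) along the
    long wall at ``target_y_cm``; it is linearly interpolated onto the
    recording's frame times.  An approach is a maximal run of frames with
    animal–target distance strictly below ``max_dist_cm`` lasting at least
    ``min_frames`` frames.  Latency is measured from the track's first
    timestamp.  Frames outside the target's presentation window or with
    missing tracking never count as close.
    """
    target_track = np.asarray(target_track, dtype=float)
    if target_track.ndim != 2 or target_track.shape[1] != 2:
        raise ValueError("target_track must be (m, 2): time_s, position_cm")
    t = rec.timestamps
    onset, offset = target_track[0, 0], target_track[-1, 0]
    pos = np.interp(t, target_track[:, 0], target_track[:, 1])
    dist = np.hypot(rec.xy[:, 0] - pos, rec.xy[:, 1] - target_y_cm)
    live = (t >= onset - 1e-12) & (t <= offset + 1e-12) & np.isfinite(dist)
    close = np.where(live, dist < max_dist_cm, False)
    runs = [(lo, hi) for lo, hi in _runs(close) if hi - lo >= min_frames]
    n = len(runs)
    latency = float(t[runs[0][0]] - onset) if runs else None
    total = sum(hi - lo for lo, hi in runs) / rec.native_rate_hz
    return ApproachStats(n=n, latency_s=latency, total_duration_s=float(total))


def ends_in_safety(
    rec: SessionRecording, zones: ZoneSet, schedule: StimulusSchedule
) -> bool:
    """True iff the animal is in either safe band during the train's last second."""
    t = rec.timestamps
    end = schedule.end_s
    sel = (t >= end - 1.0 - 1e-12) & (t < end - 1e-12)
    xy = rec.xy[sel]
    valid = np.isfinite(xy).all(axis=1)
    if not valid.any():
        return False
    xy = xy[valid]
    return bool(
        (zones.safe_zone_near.contains(xy) | zones.safe_zone_far.contains(xy)).any()
    )


def extract_trial_features(
    rec: SessionRecording,
    trace: SpeedTrace,
    schedule: StimulusSchedule,
    zones: ZoneSet,
    pre_window_s: float = 5.0,
    bouts: list[RunningBout] | None = None,
    onset_tol_s: float = 0.1,
) -> TrialFeatures:
    """Assemble the per-trial feature vector over the stimulus window.

    ``onset_tol_s`` attributes bouts starting just before the stimulus to
    the trial (smoothing advances measured onsets by up to two frames).
    """
    onset = schedule.onset_s
    end = schedule.end_s
    if bouts is None:
        bouts = detect_bouts(trace)
    window_bouts = [b for b in bouts if b.start_s >= onset - onset_tol_s - 1e-9 and b.start_s < end]
    sm = shelter_metrics(rec, onset, end)
    occ = zone_occupancy(rec, zones, onset - pre_window_s, onset)
    stats = ApproachStats(0, None, 0.0)
    if schedule.point_track is not None:
        stats = detect_approaches(rec, schedule.point_track)
    pre_vals = trace.window_values(onset - pre_window_s, onset)
    return TrialFeatures(
        latency_run_s=latency_to_running(window_bouts, onset, tol_s=onset_tol_s),
        n_bouts=len(window_bouts),
        max_speed_5s=max_speed_window(trace, onset),
        stopping_time_s=stopping_time(trace, onset, end),
        latency_shelter_s=sm.latency_shelter_s,
        n_shelter_entries=sm.n_entries,
        frac_time_in_shelter=sm.frac_time_in_shelter,
        pre_stim_median_speed=float(np.median(pre_vals)) if len(pre_vals) else float("nan"),
        pct_time_danger=occ["danger_zone"],
        pct_time_center=occ["center_zone"],
        pct_time_shelter=occ["shelter_zone"],
        ends_in_safety=ends_in_safety(rec, zones, schedule),
        n_approaches=stats.n,
        approach_latency_s=stats.latency_s,
        approach_total_s=stats.total_duration_s,
    )
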