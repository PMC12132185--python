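"""Arena geometry, session data model, and file I/O.

The experimental arena is a 35 x 82.5 cm box with a triangular shelter in
one corner and a monitor overhead.  The coordinate convention used
throughout the package puts the origin at the shelter-side corner of the
arena floor: x runs along the long axis away from the shelter wall
(0 -> 82.5 cm, the direction a virtual cricket travels), y along the short
axis (0 -> 35 cm).

Three file dialects are supported:

* pose-tracking CSV exports with the three-row header convention
  (``scorer`` / ``bodyparts`` / ``coords``) and an (x, y, likelihood)
  column triplet per tracked bodypart;
* a plain session CSV (``time_s,x_cm,y_cm``) with ``#``-prefixed metadata
  header lines, which round-trips :class:`SessionRecording` losslessly;
* stimulus schedules as JSON or YAML mappings.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaConfig",
    "Zone",
    "ZoneSet",
    "SessionRecording",
    "BodypartTracks",
    "StimulusSchedule",
    "FormatError",
    "EmptyRecordingError",
    "read_dlc_csv",
    "write_dlc_csv",
    "consensus_center",
    "read_session",
    "write_session",
    "read_schedule",
    "write_schedule",
]

SESSION_CSV_VERSION = 1

#: repetition counts printed for each stimulus type
DEFAULT_N_REPS = {"black_loom": 10, "white_loom": 5, "dimming": 5, "sweep": 1, "cricket": 1}


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class EmptyRecordingError(ValueError):
    """No usable frames remain after consensus filtering."""


@dataclass(frozen=True)
class ArenaConfig:
    """Arena floor geometry in cm, origin at the shelter-side corner."""

    length_cm: float = 82.5
    width_cm: float = 35.0
    #: 2-D points (cm) marking the shelter edge; default is a triangular
    #: shelter of 12 cm legs tucked into the origin corner.
    shelter_corners: tuple[tuple[float, float], ...] = ((0.0, 0.0), (12.0, 0.0), (0.0, 12.0))

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if len(self.shelter_corners) == 0:
            raise ValueError("at least one shelter corner is required")
        for cx, cy in self.shelter_corners:
            if not (0 <= cx <= self.length_cm and 0 <= cy <= self.width_cm):
                raise ValueError(f"shelter corner ({cx}, {cy}) outside arena")
        object.__setattr__(
            self, "shelter_corners", tuple((float(a), float(b)) for a, b in self.shelter_corners)
        )

    @property
    def shelter_xy(self) -> np.ndarray:
        return np.asarray(self.shelter_corners, dtype=float)

    def contains(self, xy: np.ndarray, tol_cm: float = 1.0) -> np.ndarray:
        """Boolean mask of points inside the arena rectangle (± tol for jitter)."""
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= -tol_cm)
            & (xy[..., 0] <= self.length_cm + tol_cm)
            & (xy[..., 1] >= -tol_cm)
            & (xy[..., 1] <= self.width_cm + tol_cm)
        )


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular zone with half-open membership [lo, hi)."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= self.x_lo)
            & (xy[..., 0] < self.x_hi)
            & (xy[..., 1] >= self.y_lo)
            & (xy[..., 1] < self.y_hi)
        )


@dataclass(frozen=True)
class ZoneSet:
    """The named arena regions used for occupancy and safety metrics.

    ``threat_zone`` is the farthest third of the arena from the shelter
    (stimuli are triggered on entry); ``danger_zone`` the half opposite the
    shelter; ``center_zone`` the central half on each axis; ``shelter_zone``
    a 23 cm square at the shelter corner; the two safe zones are bands along
    the short walls (20 cm at the shelter end, 10 cm at the far end).
    """

    threat_zone: Zone
    danger_zone: Zone
    center_zone: Zone
    shelter_zone: Zone
    safe_zone_near: Zone
    safe_zone_far: Zone

    @classmethod
    def from_arena(
        cls,
        arena: ArenaConfig,
        shelter_side_cm: float = 23.0,
        safe_near_cm: float = 20.0,
        safe_far_cm: float = 10.0,
    ) -> "ZoneSet":
        L, W = arena.length_cm, arena.width_cm
        return cls(
            threat_zone=Zone(2 * L / 3, L, 0.0, W),
            danger_zone=Zone(L / 2, L, 0.0, W),
            center_zone=Zone(L / 4, 3 * L / 4, W / 4, 3 * W / 4),
            shelter_zone=Zone(0.0, shelter_side_cm, 0.0, shelter_side_cm),
            safe_zone_near=Zone(0.0, safe_near_cm, 0.0, W),
            safe_zone_far=Zone(L - safe_far_cm, L, 0.0, W),
        )

    def as_dict(self) -> dict[str, Zone]:
        return {
            "threat_zone": self.threat_zone,
            "danger_zone": self.danger_zone,
            "center_zone": self.center_zone,
            "shelter_zone": self.shelter_zone,
            "safe_zone_near": self.safe_zone_near,
            "safe_zone_far": self.safe_zone_far,
        }


@dataclass
class SessionRecording:
    """A time-stamped 2-D center-of-mass track with arena geometry and metadata.

    ``xy`` rows may be NaN where tracking failed (missing frames).
    """

    timestamps: np.ndarray
    xy: np.ndarray
    native_rate_hz: float
    species_tag: str = "unknown"
    light_condition: str = "bright"
    arena: ArenaConfig = field(default_factory=ArenaConfig)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if len(self.timestamps) != len(self.xy):
            raise ValueError("timestamps and xy must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.native_rate_hz <= 0:
            raise ValueError("native_rate_hz must be positive")
        finite = np.isfinite(self.xy).all(axis=1)
        if finite.any() and not self.arena.contains(self.xy[finite]).all():
            raise ValueError("finite positions must lie inside the arena (±1 cm)")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.xy).all(axis=1)


@dataclass
class BodypartTracks:
    """Per-bodypart pixel tracks (x_px, y_px, likelihood) on a shared frame index."""

    data: pd.DataFrame  # MultiIndex columns (bodypart, coord)
    scorer: str = "loomkit"

    def __post_init__(self) -> None:
        lk = self.data.xs("likelihood", axis=1, level=1)
        vals = lk.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def positions(self, part: str) -> np.ndarray:
        return self.data[part][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[part]["likelihood"].to_numpy(dtype=float)


@dataclass
class StimulusSchedule:
    """A typed stimulus train: onset, repetitions, cycle structure.

    Looming and dimming stimuli repeat on a 1 s cycle (0.5 s active phase
    + 0.5 s grey screen).  Sweep and cricket stimuli are single passes with
    a moving-point track (time_s, position) — degrees for the sweep,
    cm along the long wall for the cricket.
    """

    kind: str
    onset_s: float = 0.0
    n_reps: int = 1
    cycle_s: float = 1.0
    active_s: float = 0.5
    point_track: np.ndarray | None = None  # (m, 2): time_s, position

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_N_REPS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (self.cycle_s >= self.active_s > 0):
            raise ValueError("need cycle_s >= active_s > 0")
        if self.point_track is not None:
            self.point_track = np.asarray(self.point_track, dtype=float)
            pos = self.point_track[:, 1]
            if np.any(np.diff(pos) < 0):
                raise ValueError("point_track position must be monotone non-decreasing")

    @property
    def onsets_s(self) -> np.ndarray:
        """Onset time of every repetition."""
        return self.onset_s + self.cycle_s * np.arange(self.n_reps)

    @property
    def duration_s(self) -> float:
        if self.point_track is not None and len(self.point_track):
            return float(self.point_track[-1, 0] - self.onset_s)
        return self.n_reps * self.cycle_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "onset_s": self.onset_s,
            "n_reps": self.n_reps,
            "cycle_s": self.cycle_s,
            "active_s": self.active_s,
        }
        if self.point_track is not None:
            d["point_track"] = [[float(t), float(p)] for t, p in self.point_track]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        d = dict(d)
        pt = d.pop("point_track", None)
        return cls(point_track=np.asarray(pt, dtype=float) if pt is not None else None, **d)


# ---------------------------------------------------------------------------
# pose-tracking CSV dialect
# ---------------------------------------------------------------------------

def read_dlc_csv(path) -> BodypartTracks:
    """Read a pose-tracking CSV with the three-row scorer/bodyparts/coords header.

    Columns are kept in file order; nothing is filtered here — low-likelihood
    points pass through untouched for :func:`consensus_center` to handle.
    """
    raw = pd.read_csv(path, header=None, dtype=str)
    if len(raw) < 4:
        raise FormatError("file too short for a 3-row header plus data")
    labels = [str(raw.iat[i, 0]).strip().lower() for i in range(3)]
    expected = ["scorer", "bodyparts", "coords"]
    for i, (got, want) in enumerate(zip(labels, expected)):
        if got != want:
            raise FormatError(f"header row {i + 1} must be labelled {want!r}, found {got!r}")
    scorer = str(raw.iat[0, 1])
    parts_row = [str(v) for v in raw.iloc[1, 1:]]
    coords_row = [str(v).strip().lower() for v in raw.iloc[2, 1:]]
    if len(coords_row) % 3 != 0:
        raise FormatError("coords row must hold x,y,likelihood triplets")
    parts: list[str] = []
    for j in range(0, len(coords_row), 3):
        if coords_row[j : j + 3] != ["x", "y", "likelihood"]:
            raise FormatError(
                f"coords row columns {j + 2}-{j + 4} must be x,y,likelihood, "
                f"found {coords_row[j:j + 3]}"
            )
        if not (parts_row[j] == parts_row[j + 1] == parts_row[j + 2]):
            raise FormatError(f"bodyparts row disagrees within triplet at column {j + 2}")
        parts.append(parts_row[j])

    body = raw.iloc[3:].reset_index(drop=True)
    numeric = pd.DataFrame(index=body.index)
    for j in range(1, body.shape[1]):
        col = pd.to_numeric(body.iloc[:, j], errors="coerce")
        bad = col.isna() & body.iloc[:, j].notna() & (body.iloc[:, j].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"non-numeric cell at data row {row + 4}, column {j + 1}: "
                f"{body.iat[row, j]!r}"
            )
        numeric[j] = col
    cols = pd.MultiIndex.from_tuples(
        [(p, c) for p in parts for c in ("x", "y", "likelihood")],
        names=["bodyparts", "coords"],
    )
    numeric.columns = cols
    return BodypartTracks(data=numeric, scorer=scorer)


def write_dlc_csv(tracks: BodypartTracks, path) -> None:
    """Write tracks back in the three-row-header dialect (used for fixtures)."""
    parts = tracks.bodyparts
    with open(path, "w", newline="") as fh:
        fh.write("scorer," + ",".join([tracks.scorer] * 3 * len(parts)) + "\n")
        fh.write("bodyparts," + ",".join(p for p in parts for _ in range(3)) + "\n")
        fh.write("coords," + ",".join(["x", "y", "likelihood"] * len(parts)) + "\n")
        arr = tracks.data.to_numpy(dtype=float)
        for i in range(len(arr)):
            fh.write(str(i) + "," + ",".join(_fmt(v) for v in arr[i]) + "\n")


def _fmt(v: float) -> str:
    if not math.isfinite(v):
        return "nan"
    return format(float(v), ".12g")


def consensus_center(
    tracks: BodypartTracks,
    min_likelihood: float = 0.9,
    px_per_cm: float = 10.0,
    max_gap_frames: int = 20,
    native_rate_hz: float = 30.0,
    arena: ArenaConfig | None = None,
    **session_kwargs,
) -> SessionRecording:
    """Consensus center of mass: per-frame mean of confidently tracked bodyparts.

    A frame where no bodypart reaches ``min_likelihood`` is missing; runs of
    up to ``max_gap_frames`` missing frames are bridged by linear
    interpolation, longer runs (and leading/trailing gaps) stay NaN.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    parts = tracks.bodyparts
    if not parts:
        raise ValueError("at least one bodypart is required")
    n = tracks.n_frames
    pos = np.stack([tracks.positions(p) for p in parts])  # (P, n, 2)
    lk = np.stack([tracks.likelihood(p) for p in parts])  # (P, n)
    ok = (lk >= min_likelihood) & np.isfinite(pos).all(axis=2)
    w = ok[..., None].astype(float)
    with np.errstate(invalid="ignore"):
        center = (pos * w).sum(axis=0) / w.sum(axis=0)
    center = center / px_per_cm

    missing = ~ok.any(axis=0)
    if missing.all():
        raise EmptyRecordingError("no frame has any bodypart above min_likelihood")
    center = _interpolate_gaps(center, missing, max_gap_frames)

    timestamps = np.arange(n) / native_rate_hz
    return SessionRecording(
        timestamps=timestamps,
        xy=center,
        native_rate_hz=native_rate_hz,
        arena=arena if arena is not None else ArenaConfig(),
        **session_kwargs,
    )


def _interpolate_gaps(xy: np.ndarray, missing: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly bridge interior missing runs of length <= max_gap."""
    out = xy.copy()
    idx = np.arange(len(xy))
    valid = ~missing
    edges = np.flatnonzero(np.diff(np.concatenate(([False], missing, [False]))))
    for lo, hi in zip(edges[::2], edges[1::2]):  # [lo, hi) is a missing run
        interior = lo > 0 and hi < len(xy)
        if interior and (hi - lo) <= max_gap:
            for d in range(2):
                out[lo:hi, d] = np.interp(idx[lo:hi], idx[valid], xy[valid, d])
        else:
            out[lo:hi] = np.nan
    return out


# ---------------------------------------------------------------------------
# plain session CSV
# ---------------------------------------------------------------------------

def write_session(rec: SessionRecording, path) -> None:
    """Write a session as a plain CSV with ``#`` metadata header (lossless)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# session_csv_version: {SESSION_CSV_VERSION}\n")
        fh.write(f"# native_rate_hz: {_fmt(rec.native_rate_hz)}\n")
        fh.write(f"# species_tag: {rec.species_tag}\n")
        fh.write(f"# light_condition: {rec.light_condition}\n")
        fh.write(f"# arena_length_cm: {_fmt(rec.arena.length_cm)}\n")
        fh.write(f"# arena_width_cm: {_fmt(rec.arena.width_cm)}\n")
        corners = ";".join(f"{_fmt(x)},{_fmt(y)}" for x, y in rec.arena.shelter_corners)
        fh.write(f"# shelter_corners: {corners}\n")
        fh.write("time_s,x_cm,y_cm\n")
        for t, (x, y) in zip(rec.timestamps, rec.xy):
            fh.write(f"{_fmt(t)},{_fmt(x)},{_fmt(y)}\n")


def read_session(path) -> SessionRecording:
    """Read a session CSV written by :func:`write_session`."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line:
                rows.append(line)
    version = int(meta.get("session_csv_version", "-1"))
    if version != SESSION_CSV_VERSION:
        raise FormatError(
            f"session CSV version {version} not supported (expected {SESSION_CSV_VERSION})"
        )
    df = pd.read_csv(io.StringIO("\n".join(rows)))
    corners = tuple(
        tuple(float(v) for v in pair.split(",")) for pair in meta["shelter_corners"].split(";")
    )
    arena = ArenaConfig(
        length_cm=float(meta["arena_length_cm"]),
        width_cm=float(meta["arena_width_cm"]),
        shelter_corners=corners,
    )
    return SessionRecording(
        timestamps=df["time_s"].to_numpy(float),
        xy=df[["x_cm", "y_cm"]].to_numpy(float),
        native_rate_hz=float(meta["native_rate_hz"]),
        species_tag=meta.get("species_tag", "unknown"),
        light_condition=meta.get("light_condition", "bright"),
        arena=arena,
    )


# ---------------------------------------------------------------------------
# stimulus schedule files
# ---------------------------------------------------------------------------

def write_schedule(schedule: StimulusSchedule, path) -> None:
    path = str(path)
    d = schedule.to_dict()
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=1)


def read_schedule(path) -> StimulusSchedule:
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return StimulusSchedule.from_dict(d)
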