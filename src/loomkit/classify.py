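"""Kinematics-based surrogate for manual five-category behavior scoring.

Trials are scored into one of six labels — ``stop`` (freezing), ``escape``
(one strong run, typically shelter-directed, then stopping), ``dart_safety``
and ``dart`` (multiple sprints in varying directions, split by whether the
trial ends in a safe zone), ``weak`` (sub-threshold speed transient) and
``none`` — by a deterministic rule cascade over the stimulus window.
Precedence is dart > escape > stop > weak > none.  Every label carries the
list of rules that fired so borderline trials can be audited.

The ``weak`` class here captures only sub-threshold speed transients;
startles expressed as rearing toward the stimulus are invisible to
center-of-mass kinematics and are not recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import SessionRecording, StimulusSchedule, ZoneSet
from .events import (
    RunningBout,
    TrialFeatures,
    ends_in_safety as _ends_in_safety,
)
from .kinematics import SpeedTrace

__all__ = [
    "LABELS",
    "BehaviorLabel",
    "ClassifierConfig",
    "classify_trial",
    "cohort_summary",
    "habituation_curve",
]

LABELS = ("stop", "escape", "dart_safety", "dart", "weak", "none")


@dataclass(frozen=True)
class BehaviorLabel:
    value: str
    confidence: float = 1.0
    rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value not in LABELS:
            raise ValueError(f"unknown label {self.value!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the rule cascade (defaults mirror the assay)."""

    still_time_s: float = 1.0        # minimal stillness to call a stop
    burst_span_s: float = 1.5        # an escape's bouts all fit in this span
    heading_change_deg: float = 60.0  # sprint direction change for darts
    weak_speed_cm_s: float = 15.0    # weak-transient crossing level
    weak_max_frames: int = 3         # transient must be < this many frames
    post_still_speed_cm_s: float = 5.0  # post-bout stillness level
    onset_tol_s: float = 0.1         # pre-onset grace for smoothed bout starts


def _bout_heading(rec: SessionRecording, bout: RunningBout) -> float | None:
    """Net displacement direction over a bout, in radians; None if degenerate."""
    t = rec.timestamps
    sel = np.flatnonzero((t >= bout.start_s - 1e-9) & (t <= bout.end_s + 1e-9))
    if len(sel) < 2:
        return None
    p0, p1 = rec.xy[sel[0]], rec.xy[sel[-1]]
    if not (np.isfinite(p0).all() and np.isfinite(p1).all()):
        return None
    d = p1 - p0
    if np.hypot(*d) < 1e-9:
        return None
    return math.atan2(d[1], d[0])


def _heading_change_deg(a: float, b: float) -> float:
    d = abs(a - b) % (2 * math.pi)
    return math.degrees(min(d, 2 * math.pi - d))


def classify_trial(
    features: TrialFeatures,
    bouts: list[RunningBout],
    rec: SessionRecording,
    zones: ZoneSet,
    schedule: StimulusSchedule,
    trace: SpeedTrace,
    config: ClassifierConfig = ClassifierConfig(),
) -> BehaviorLabel:
    """Deterministic rule cascade over the stimulus window.

    Dart rules fire first (≥ 2 temporally separated bouts with a > 60°
    heading change between consecutive sprints, split into
    ``dart_safety``/``dart`` by the safe-zone ending), then escape (a
    single bout, or several within one ≤ 1.5 s burst span, followed by
    stillness or a shelter entry), then stop, weak, none.  Trials with
    sprints that fit neither dart nor the strict escape rule fall back to
    ``escape`` at reduced confidence, with the fallback noted in the rule
    trace.
    """
    onset, end = schedule.onset_s, schedule.end_s
    if end - onset < 1.0:
        raise ValueError("stimulus window shorter than 1 s")
    rules: list[str] = []
    window_bouts = sorted(
        (b for b in bouts if onset - config.onset_tol_s - 1e-9 <= b.start_s < end),
        key=lambda b: b.start_s,
    )

    if len(window_bouts) >= 2:
        headings = [_bout_heading(rec, b) for b in window_bouts]
        turns = [
            _heading_change_deg(h0, h1)
            for h0, h1 in zip(headings[:-1], headings[1:])
            if h0 is not None and h1 is not None
        ]
        if turns and max(turns) > config.heading_change_deg:
            rules.append(f"dart: {len(window_bouts)} sprints, max turn {max(turns):.0f} deg")
            if features.ends_in_safety:
                rules.append("dart ends in safe zone")
                return BehaviorLabel("dart_safety", 1.0, tuple(rules))
            return BehaviorLabel("dart", 1.0, tuple(rules))
        rules.append("multiple sprints without >60 deg turn")

    if len(window_bouts) >= 1:
        span = window_bouts[-1].end_s - window_bouts[0].start_s
        last_end = window_bouts[-1].end_s
        post = trace.window_values(last_end, end)
        still_after = len(post) == 0 or float(np.median(post)) < config.post_still_speed_cm_s
        sheltered = features.latency_shelter_s is not None
        if span <= config.burst_span_s and (still_after or sheltered):
            rules.append("escape: one sprint burst + stillness or shelter entry")
            return BehaviorLabel("escape", 1.0, tuple(rules))
        rules.append("escape fallback: sprints without a matching dart/escape pattern")
        return BehaviorLabel("escape", 0.5, tuple(rules))

    if features.stopping_time_s >= config.still_time_s:
        rules.append(f"stop: {features.stopping_time_s:.2f} s stillness, no sprint")
        return BehaviorLabel("stop", 1.0, tuple(rules))

    vals = trace.window_values(onset, end)
    above = vals > config.weak_speed_cm_s
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    runs = list(zip(edges[::2], edges[1::2]))
    if any(0 < hi - lo < config.weak_max_frames for lo, hi in runs):
        rules.append("weak: sub-threshold speed transient")
        return BehaviorLabel("weak", 0.7, tuple(rules))

    rules.append("none: no rule fired")
    return BehaviorLabel("none", 1.0, tuple(rules))


def cohort_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of each behavior label per condition.

    ``labels`` needs columns ``species``, ``light``, ``stimulus``,
    ``label``.  Fractions within each condition sum to 1; a condition with
    no trials simply has no rows (never 0/0).
    """
    required = {"species", "light", "stimulus", "label"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"labels table missing columns: {sorted(missing)}")
    counts = (
        labels.groupby(["species", "light", "stimulus", "label"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["species", "light", "stimulus"], observed=True)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def habituation_curve(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of animals responding at each repetition of the stimulus train.

    ``trials`` needs columns ``animal``, ``repetition``, ``label`` and an
    optional boolean ``tested`` (False once an animal is excluded, e.g. by
    the >10-min shelter rule).  Responding means label != "none"; the
    denominator at each repetition is the number of animals still tested.
    """
    df = trials.copy()
    if "tested" not in df.columns:
        df["tested"] = True
    out = []
    for rep, grp in df.groupby("repetition", observed=True):
        tested = grp[grp["tested"]]
        n = len(tested)
        responding = int((tested["label"] != "none").sum())
        out.append(
            {
                "repetition": rep,
                "n_tested": n,
                "n_responding": responding,
                "pct_responding": 100.0 * responding / n if n else float("nan"),
            }
        )
    return pd.DataFrame(out).sort_values("repetition").reset_index(drop=True)
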