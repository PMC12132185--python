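"""Synthetic arena sessions with known ground-truth behavior programs.

The generator produces stimulus schedules exactly as the assay presents
them (a black looming disk expanding for 0.5 s then 0.5 s of grey,
repeated 10×; white looming and dimming repeated 5×; a 21°/s sweep; a
virtual cricket crawling the 83 cm long wall at 3 cm/s) and
center-of-mass trajectories from programmable behavior programs:

* ``forage_only`` — a bounded correlated random walk for the whole session;
* ``freeze`` — foraging until a light-dependent latency after stimulus
  onset, then near-complete immobility for the rest of the train;
* ``escape_shelter`` — one smooth sprint to the shelter corner with a
  logistic speed profile, then sheltering;
* ``dart`` / ``dart_safety`` — short straight sprints with fresh random
  headings launched at loom onsets (± configurable jitter), optional
  intermediate sprints mid-cycle, ending mid-arena or steered into a safe
  zone during the train's last second.

Light level modulates the generator in the directions seen in the assay:
dim light means slower foraging but faster pre-stimulus (threat-zone)
movement, shorter response latencies, and more intermediate sprints.
Magnitudes are configuration, not measurements.  Every draw comes from a
single seeded generator, so sessions are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import (
    ArenaConfig,
    DEFAULT_N_REPS,
    SessionRecording,
    StimulusSchedule,
    ZoneSet,
)

__all__ = [
    "BehaviorProgram",
    "CohortConfig",
    "SimulatedTrial",
    "build_schedule",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_habituation",
    "default_program",
    "DEFAULT_MIX",
]

PROGRAM_KINDS = ("forage_only", "freeze", "escape_shelter", "dart", "dart_safety")

#: default behavior-program composition of a labelled cohort
DEFAULT_MIX = {
    "freeze": 0.25,
    "escape_shelter": 0.25,
    "dart_safety": 0.20,
    "dart": 0.15,
    "forage_only": 0.15,
}


@dataclass(frozen=True)
class BehaviorProgram:
    """Ground-truth motion program for one trial."""

    kind: str
    latency_median_s: float = 1.0     # lognormal median of response latency
    latency_sigma: float = 0.35       # lognormal shape of the latency
    peak_speed_median: float = 65.0   # cm/s, lognormal median of sprint peaks
    peak_speed_sigma: float = 0.15
    loom_lock: bool = False           # sprint onsets drawn at loom onsets
    onset_jitter_s: float = 0.0       # SD of jitter around loom onsets
    p_intermediate: float = 0.3       # extra brief sprint between looms
    sprint_duration_s: float = 0.4    # loom-locked sprint length
    intermediate_duration_s: float = 0.2  # between-loom sprints are briefer
    end_target: str = "none"          # none | shelter | safe_zone

    def __post_init__(self) -> None:
        if self.kind not in PROGRAM_KINDS:
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.onset_jitter_s < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort."""

    n_per_condition: int = 100
    species: tuple[str, ...] = ("Mm", "Pm", "Pp")
    lights: tuple[str, ...] = ("dim", "bright")
    rate_hz: float = 30.0
    pre_stimulus_s: float = 10.0
    post_stimulus_s: float = 2.0
    seed: int = 0
    #: lognormal medians of per-frame foraging speed (cm/s) by light level;
    #: foraging slows under dim light
    forage_speed_median: dict = field(
        default_factory=lambda: {"dim": 3.5, "bright": 5.0}
    )
    #: threat-zone approach speed in the pre-stimulus window; faster in dim
    prestim_speed_median: dict = field(
        default_factory=lambda: {"dim": 9.0, "bright": 6.0}
    )
    speed_sigma: float = 0.5          # lognormal shape of CRW speeds
    heading_persistence: float = 0.8  # CRW rho in [0, 1)

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if not (0 <= self.heading_persistence < 1):
            raise ValueError("heading persistence must lie in [0, 1)")


@dataclass
class SimulatedTrial:
    recording: SessionRecording
    schedule: StimulusSchedule
    true_label: str
    true_latency_s: float | None
    program: BehaviorProgram


# ---------------------------------------------------------------------------
# stimulus schedules
# ---------------------------------------------------------------------------

def build_schedule(kind: str, onset_s: float = 0.0, **params) -> StimulusSchedule:
    """Stimulus schedule with the printed repetition and cycle structure.

    black_loom: 10 reps of 0.5 s expansion + 0.5 s grey; white_loom and
    dimming: 5 reps of the same cycle; sweep: one pass at 21°/s (track in
    degrees over ``span_deg``); cricket: one pass at 3 cm/s from 0 to
    ``span_cm`` (83 cm) along the long wall.
    """
    if kind in ("black_loom", "white_loom", "dimming"):
        return StimulusSchedule(
            kind=kind,
            onset_s=onset_s,
            n_reps=params.pop("n_reps", DEFAULT_N_REPS[kind]),
            cycle_s=params.pop("cycle_s", 1.0),
            active_s=params.pop("active_s", 0.5),
        )
    if kind == "sweep":
        speed = params.pop("deg_per_s", 21.0)
        span = params.pop("span_deg", 90.0)
        dur = span / speed
        tt = np.linspace(0.0, dur, int(round(dur * 60)) + 1)
        track = np.column_stack([onset_s + tt, speed * tt])
        return StimulusSchedule(
            kind=kind, onset_s=onset_s, n_reps=1, cycle_s=dur, active_s=dur, point_track=track
        )
    if kind == "cricket":
        speed = params.pop("cm_per_s", 3.0)
        span = params.pop("span_cm", 83.0)
        dur = span / speed
        tt = np.linspace(0.0, dur, int(round(dur * 30)) + 1)
        track = np.column_stack([onset_s + tt, np.minimum(speed * tt, span)])
        return StimulusSchedule(
            kind=kind, onset_s=onset_s, n_reps=1, cycle_s=dur, active_s=dur, point_track=track
        )
    raise ValueError(f"unknown stimulus kind {kind!r}")


# ---------------------------------------------------------------------------
# trajectory pieces
# ---------------------------------------------------------------------------

def _reflect(p: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    q = (p - lo) % (2 * span)
    return lo + (span - abs(q - span))


def _crw_step(
    xy: np.ndarray,
    heading: float,
    speed_median: float,
    sigma: float,
    rho: float,
    dt: float,
    arena: ArenaConfig,
    rng: np.random.Generator,
    margin: float = 1.0,
) -> tuple[np.ndarray, float]:
    """One correlated-random-walk step with reflecting walls."""
    heading = heading + (1.0 - rho) * math.pi * rng.normal()
    speed = speed_median * math.exp(sigma * rng.normal())
    nx = xy[0] + speed * dt * math.cos(heading)
    ny = xy[1] + speed * dt * math.sin(heading)
    rx = _reflect(nx, margin, arena.length_cm - margin)
    ry = _reflect(ny, margin, arena.width_cm - margin)
    if rx != nx or ry != ny:  # bounce: flip the heading component that hit
        heading = math.atan2(
            (ry - xy[1]) if abs(ry - ny) > 1e-12 else (ny - xy[1]),
            (rx - xy[0]) if abs(rx - nx) > 1e-12 else (nx - xy[0]),
        )
        heading = math.atan2(ry - xy[1], rx - xy[0])
    return np.array([rx, ry]), heading


def _sprint_profile(n: int, peak: float) -> np.ndarray:
    """Fast-attack sprint speed profile: peak speed held for the whole sprint."""
    return np.full(n, peak)


def _sprint_to(
    xy: np.ndarray, target: np.ndarray, peak: float, n: int, dt: float, arena: ArenaConfig
) -> np.ndarray:
    """Positions of an n-frame sprint from xy toward target (clipped at target)."""
    prof = _sprint_profile(n, peak)
    out = np.empty((n, 2))
    pos = xy.astype(float).copy()
    for i in range(n):
        d = target - pos
        dist = float(np.hypot(*d))
        step = min(prof[i] * dt, dist)
        if dist > 1e-9:
            pos = pos + d / dist * step
        out[i] = pos
    out[:, 0] = np.clip(out[:, 0], 0.5, arena.length_cm - 0.5)
    out[:, 1] = np.clip(out[:, 1], 0.5, arena.width_cm - 0.5)
    return out


def _shelter_target(arena: ArenaConfig) -> np.ndarray:
    """A point just inside the shelter, < 5 cm from its nearest corner."""
    centroid = arena.shelter_xy.mean(axis=0)
    corners = np.array(
        [
            [0.0, 0.0],
            [arena.length_cm, 0.0],
            [0.0, arena.width_cm],
            [arena.length_cm, arena.width_cm],
        ]
    )
    wall = corners[np.argmin(np.linalg.norm(corners - centroid, axis=1))]
    return centroid + 0.6 * (wall - centroid)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def default_program(kind: str, light: str, rng: np.random.Generator | None = None) -> BehaviorProgram:
    """Program defaults with light-level modulation in the assay's directions."""
    dim = light == "dim"
    if kind == "freeze":
        return BehaviorProgram("freeze", latency_median_s=0.8 if dim else 1.2)
    if kind == "escape_shelter":
        return BehaviorProgram(
            "escape_shelter",
            latency_median_s=0.6 if dim else 1.2,
            peak_speed_median=75.0 if dim else 60.0,
            end_target="shelter",
        )
    if kind in ("dart", "dart_safety"):
        return BehaviorProgram(
            kind,
            latency_median_s=0.0,
            peak_speed_median=70.0 if dim else 60.0,
            loom_lock=True,
            onset_jitter_s=0.0,
            p_intermediate=0.45 if dim else 0.25,
            end_target="safe_zone" if kind == "dart_safety" else "none",
        )
    if kind == "forage_only":
        return BehaviorProgram("forage_only")
    raise ValueError(f"unknown program kind {kind!r}")


def simulate_trajectory(
    program: BehaviorProgram,
    schedule: StimulusSchedule,
    arena: ArenaConfig,
    cfg: CohortConfig,
    seed: int | np.random.Generator,
    light: str = "bright",
    species: str = "Mm",
) -> SimulatedTrial:
    """One session: CRW foraging, then the program's stimulus response.

    The pre-stimulus phase is a bounded correlated random walk whose speed
    distribution switches from the foraging to the (faster, light-
    dependent) threat-zone approach regime in the last 8 s before onset.
    Ground truth (label, response latency) is returned with the recording.
    """
    if program.kind in ("dart", "dart_safety") and schedule.n_reps < 2:
        raise ValueError("dart programs require a repetitive stimulus schedule")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / cfg.rate_hz
    onset = schedule.onset_s
    t_start = onset - cfg.pre_stimulus_s
    t_end = schedule.onset_s + schedule.n_reps * schedule.cycle_s + cfg.post_stimulus_s
    n = int(round((t_end - t_start) * cfg.rate_hz))
    times = t_start + np.arange(n) * dt
    xy = np.empty((n, 2))

    # start mid-arena, biased toward the threat zone (where stimuli trigger)
    xy[0] = (
        rng.uniform(0.55, 0.9) * arena.length_cm,
        rng.uniform(0.25, 0.75) * arena.width_cm,
    )
    heading = rng.uniform(-math.pi, math.pi)
    forage_med = cfg.forage_speed_median[light]
    prestim_med = cfg.prestim_speed_median[light]

    latency = None
    if program.kind != "forage_only":
        latency = float(
            program.latency_median_s * math.exp(program.latency_sigma * rng.normal())
        )
        if program.loom_lock:
            # snap to the first loom onset at/after the drawn latency
            k = int(np.searchsorted(schedule.onsets_s - onset, latency - 1e-9))
            k = min(k, schedule.n_reps - 1)
            latency = float(schedule.onsets_s[k] - onset)
            if program.onset_jitter_s > 0:
                latency = max(0.0, latency + program.onset_jitter_s * rng.normal())
    respond_t = onset + latency if latency is not None else math.inf

    i = 1
    # --- foraging / threat-zone approach up to the response time ----------
    while i < n and times[i] < respond_t:
        med = prestim_med if times[i] >= onset - 8.0 else forage_med
        xy[i], heading = _crw_step(
            xy[i - 1], heading, med, cfg.speed_sigma, cfg.heading_persistence, dt, arena, rng
        )
        i += 1

    if program.kind == "forage_only":
        pass
    elif program.kind == "freeze":
        while i < n:
            xy[i] = xy[i - 1] + rng.normal(0.0, 0.01, size=2)
            i += 1
    elif program.kind == "escape_shelter":
        peak = program.peak_speed_median * math.exp(program.peak_speed_sigma * rng.normal())
        xy[i:] = _sprint_to(xy[max(i - 1, 0)], _shelter_target(arena), peak, n - i, dt, arena)
        i = n
    elif program.kind in ("dart", "dart_safety"):
        zones = ZoneSet.from_arena(arena)
        sprint_n = max(int(round(program.sprint_duration_s * cfg.rate_hz)), 2)
        inter_n = max(int(round(program.intermediate_duration_s * cfg.rate_hz)), 2)
        sprint_times = {onset + latency: sprint_n}
        for o in schedule.onsets_s:
            rel = o - onset
            if rel > latency + 1e-9:
                jit = program.onset_jitter_s * rng.normal() if program.onset_jitter_s else 0.0
                sprint_times[onset + rel + jit] = sprint_n
            if rel >= latency - 1e-9 and rng.random() < program.p_intermediate:
                # intermediate sprints fall between looms, not phase-locked to
                # the cycle; they are brief and end before the next loom
                u = rng.uniform(
                    program.sprint_duration_s + 0.05,
                    schedule.cycle_s - program.intermediate_duration_s - 0.05,
                )
                sprint_times[onset + rel + u] = inter_n
        train_end = onset + schedule.n_reps * schedule.cycle_s
        sprint_times = {st: sn for st, sn in sprint_times.items() if st < train_end - 0.2}
        last_sprint = max(sprint_times)
        peak = program.peak_speed_median * math.exp(program.peak_speed_sigma * rng.normal())
        while i < n:
            t = times[i]
            due = [st for st in sprint_times if abs(st - t) < 0.5 * dt]
            if due:
                is_last = abs(due[0] - last_sprint) < 1e-9
                target = _dart_target(
                    xy[i - 1], arena, zones, rng,
                    final=is_last, end_target=program.end_target,
                )
                # the final sprint runs until the target is reached so the
                # trial actually ends where the program says it does
                m = (n - i) if is_last else min(sprint_times[due[0]], n - i)
                xy[i : i + m] = _sprint_to(xy[i - 1], target, peak, m, dt, arena)
                i += m
            else:
                xy[i] = xy[i - 1] + rng.normal(0.0, 0.01, size=2)
                i += 1

    rec = SessionRecording(
        timestamps=times,
        xy=xy,
        native_rate_hz=cfg.rate_hz,
        species_tag=species,
        light_condition=light,
        arena=arena,
    )
    label = {
        "forage_only": "none",
        "freeze": "stop",
        "escape_shelter": "escape",
        "dart": "dart",
        "dart_safety": "dart_safety",
    }[program.kind]
    return SimulatedTrial(rec, schedule, label, latency, program)


def _dart_target(
    xy: np.ndarray,
    arena: ArenaConfig,
    zones: ZoneSet,
    rng: np.random.Generator,
    final: bool,
    end_target: str,
) -> np.ndarray:
    """Pick a sprint target; the final sprint steers per the end target.

    Non-final targets are drawn so consecutive sprints turn by a wide angle
    (uniform over the arena interior, rejected if nearly collinear with the
    current position's direction is unnecessary — uniform redraws give >60°
    turns with high probability, and the classifier only needs one).
    """
    L, W = arena.length_cm, arena.width_cm
    if final and end_target == "safe_zone":
        # steer into whichever safe band is closer so the sprint arrives in time
        near, far = zones.safe_zone_near, zones.safe_zone_far
        band = near if abs(xy[0] - near.x_hi) < abs(far.x_lo - xy[0]) else far
        return np.array(
            [rng.uniform(band.x_lo + 2, band.x_hi - 2), np.clip(xy[1], 3, W - 3)]
        )
    if final and end_target == "shelter":
        return _shelter_target(arena)
    if final and end_target == "none":
        # finish mid-arena, clear of both safe bands
        return np.array([rng.uniform(0.35 * L, 0.6 * L), rng.uniform(3, W - 3)])
    # intermediate sprints stay clear of the safe bands (they are short and
    # would otherwise park the animal in a band near the train's end) and
    # target a point far enough that the sprint runs its full duration
    # instead of stalling at the target
    for _ in range(40):
        cand = np.array([rng.uniform(0.25 * L, 0.7 * L), rng.uniform(2, W - 2)])
        if np.hypot(*(cand - xy)) > 22.0:
            return cand
    return cand


def simulate_cohort(
    cfg: CohortConfig,
    mix: dict[str, float] | None = None,
    schedule_kind: str = "black_loom",
) -> tuple[list[SimulatedTrial], pd.DataFrame]:
    """A labelled cohort: per condition, program composition matches ``mix`` exactly.

    Fractions are converted to integer counts by largest remainder, so the
    requested composition holds trial-for-trial.  Returns the trials plus a
    tidy ground-truth table.
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    rng = np.random.default_rng(cfg.seed)
    arena = ArenaConfig()
    trials: list[SimulatedTrial] = []
    rows = []
    for species in cfg.species:
        for light in cfg.lights:
            counts = _exact_counts(mix, cfg.n_per_condition)
            kinds = [k for k, c in counts.items() for _ in range(c)]
            rng.shuffle(kinds)
            for j, kind in enumerate(kinds):
                schedule = build_schedule(schedule_kind, onset_s=cfg.pre_stimulus_s)
                program = default_program(kind, light)
                trial = simulate_trajectory(
                    program, schedule, arena, cfg, rng, light=light, species=species
                )
                trials.append(trial)
                rows.append(
                    {
                        "trial": len(trials) - 1,
                        "species": species,
                        "light": light,
                        "stimulus": schedule_kind,
                        "program": kind,
                        "true_label": trial.true_label,
                        "true_latency_s": trial.true_latency_s,
                    }
                )
    return trials, pd.DataFrame(rows)


def _exact_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_habituation(
    n_animals: int = 10,
    n_repetitions: int = 12,
    p_respond_initial: float = 0.95,
    decay_per_rep: float = 0.85,
    p_shelter_exclusion: float = 0.02,
    light: str = "bright",
    species: str = "Pp",
    seed: int = 0,
    cfg: CohortConfig | None = None,
) -> tuple[list[SimulatedTrial], pd.DataFrame]:
    """Repeated stimulus trains with a geometrically decaying response rate.

    Each (animal, repetition) yields one short trial; the probability of
    responding (an escape) decays as ``p0 * decay**rep``.  Under dim light
    the decay is attenuated (habituation is weaker).  Animals can drop out
    via the >10-min-shelter rule with a small per-repetition probability;
    they are marked ``tested=False`` from then on.
    """
    if light == "dim":
        decay_per_rep = min(1.0, decay_per_rep + 0.5 * (1.0 - decay_per_rep))
    rng = np.random.default_rng(seed)
    cfg = cfg or CohortConfig(seed=seed, pre_stimulus_s=6.0)
    arena = ArenaConfig()
    trials = []
    rows = []
    for a in range(n_animals):
        excluded = False
        for rep in range(n_repetitions):
            p = p_respond_initial * decay_per_rep**rep
            responds = (not excluded) and rng.random() < p
            kind = "escape_shelter" if responds else "forage_only"
            schedule = build_schedule("black_loom", onset_s=cfg.pre_stimulus_s)
            trial = simulate_trajectory(
                default_program(kind, light), schedule, arena, cfg, rng,
                light=light, species=species,
            )
            trials.append(trial)
            rows.append(
                {
                    "animal": a,
                    "repetition": rep,
                    "tested": not excluded,
                    "true_responds": responds,
                    "trial": len(trials) - 1,
                }
            )
            if not excluded and rng.random() < p_shelter_exclusion:
                excluded = True
    return trials, pd.DataFrame(rows)
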