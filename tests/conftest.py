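import numpy as np
import pytest

from loomkit.arena import ArenaConfig, SessionRecording, ZoneSet
from loomkit.kinematics import SpeedTrace
from loomkit.simulate import CohortConfig, build_schedule, default_program, simulate_trajectory


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture
def zones(arena) -> ZoneSet:
    return ZoneSet.from_arena(arena)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def loom_schedule():
    """Black looming train starting at t = 10 s (10 reps x 1 s)."""
    return build_schedule("black_loom", onset_s=10.0)


@pytest.fixture
def cohort_cfg() -> CohortConfig:
    return CohortConfig(seed=99)


def make_trace(values, rate_hz=30.0, t0_s=0.0) -> SpeedTrace:
    return SpeedTrace(rate_hz=rate_hz, t0_s=t0_s, values=np.asarray(values, float))


def make_recording(xy, rate_hz=30.0, arena=None, **kw) -> SessionRecording:
    xy = np.asarray(xy, float)
    return SessionRecording(
        timestamps=np.arange(len(xy)) / rate_hz,
        xy=xy,
        native_rate_hz=rate_hz,
        arena=arena or ArenaConfig(),
        **kw,
    )


@pytest.fixture
def dart_trial(arena, cohort_cfg, loom_schedule):
    """A zero-jitter dart-to-safety trial with its ground truth."""
    return simulate_trajectory(
        default_program("dart_safety", "dim"),
        loom_schedule,
        arena,
        cohort_cfg,
        seed=5,
        light="dim",
    )
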