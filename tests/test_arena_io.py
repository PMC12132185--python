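"""Arena geometry, session round-trips, and the pose-CSV dialect."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loomkit.arena import (
    ArenaConfig,
    BodypartTracks,
    EmptyRecordingError,
    FormatError,
    SessionRecording,
    StimulusSchedule,
    ZoneSet,
    consensus_center,
    read_dlc_csv,
    read_schedule,
    read_session,
    write_dlc_csv,
    write_schedule,
    write_session,
)


def _tracks(frames: np.ndarray, parts=("head", "tail"), likelihood=None) -> BodypartTracks:
    """frames: (P, n, 2) pixel positions."""
    cols = pd.MultiIndex.from_tuples(
        [(p, c) for p in parts for c in ("x", "y", "likelihood")],
        names=["bodyparts", "coords"],
    )
    n = frames.shape[1]
    lk = np.ones((len(parts), n)) if likelihood is None else likelihood
    data = np.concatenate(
        [np.column_stack([frames[i, :, 0], frames[i, :, 1], lk[i]]) for i in range(len(parts))],
        axis=1,
    )
    return BodypartTracks(data=pd.DataFrame(data, columns=cols))


class TestArenaGeometry:
    def test_default_dimensions(self, arena):
        assert arena.length_cm == 82.5
        assert arena.width_cm == 35.0

    def test_rejects_shelter_corner_outside(self):
        with pytest.raises(ValueError, match="outside arena"):
            ArenaConfig(shelter_corners=((90.0, 0.0),))

    def test_rejects_empty_shelter(self):
        with pytest.raises(ValueError, match="shelter corner"):
            ArenaConfig(shelter_corners=())

    def test_threat_zone_subset_of_danger_zone(self, arena, zones, rng):
        pts = np.column_stack(
            [rng.uniform(0, arena.length_cm, 500), rng.uniform(0, arena.width_cm, 500)]
        )
        in_threat = zones.threat_zone.contains(pts)
        in_danger = zones.danger_zone.contains(pts)
        assert np.all(~in_threat | in_danger)

    def test_zone_membership_deterministic_and_half_open(self, arena, zones, rng):
        pts = np.column_stack(
            [rng.uniform(0, arena.length_cm, 200), rng.uniform(0, arena.width_cm, 200)]
        )
        for zone in zones.as_dict().values():
            a = zone.contains(pts)
            b = zone.contains(pts)
            assert np.array_equal(a, b)
        # boundary: lower edge inside, upper edge outside
        cz = zones.center_zone
        assert cz.contains(np.array([cz.x_lo, cz.y_lo]))
        assert not cz.contains(np.array([cz.x_hi, cz.y_lo]))


class TestDlcDialect:
    def test_round_trip(self, tmp_path, rng):
        frames = rng.uniform(0, 300, size=(2, 3, 2))
        tracks = _tracks(frames)
        path = tmp_path / "poses.csv"
        write_dlc_csv(tracks, path)
        back = read_dlc_csv(path)
        assert back.bodyparts == ["head", "tail"]
        assert back.n_frames == 3
        np.testing.assert_allclose(back.positions("head"), frames[0], rtol=1e-10)

    def test_low_likelihood_preserved_not_filtered(self, tmp_path):
        lk = np.ones((1, 3))
        lk[0, 1] = 0.2
        tracks = _tracks(np.zeros((1, 3, 2)), parts=("body",), likelihood=lk)
        path = tmp_path / "poses.csv"
        write_dlc_csv(tracks, path)
        back = read_dlc_csv(path)
        assert back.likelihood("body")[1] == pytest.approx(0.2)

    def test_missing_likelihood_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "scorer,s,s\nbodyparts,head,head\ncoords,x,y\n0,1.0,2.0\n"
        )
        with pytest.raises(FormatError, match="x,y,likelihood"):
            read_dlc_csv(path)

    def test_wrong_header_label_names_offending_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "scorer,s,s,s\nparts,h,h,h\ncoords,x,y,likelihood\n0,1,2,0.9\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            read_dlc_csv(path)

    def test_non_numeric_cell_reports_position(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "scorer,s,s,s\nbodyparts,h,h,h\ncoords,x,y,likelihood\n"
            "0,1.0,2.0,0.9\n1,oops,2.0,0.9\n"
        )
        with pytest.raises(FormatError, match="row 5.*column 2"):
            read_dlc_csv(path)


class TestConsensusCenter:
    def test_mean_of_bodyparts(self):
        frames = np.zeros((3, 1, 2))
        frames[:, 0, 0] = [0.0, 2.0, 4.0]
        rec = consensus_center(_tracks(frames, parts=("a", "b", "c")), px_per_cm=1.0)
        np.testing.assert_allclose(rec.xy[0], [2.0, 0.0])

    def test_low_likelihood_part_excluded(self):
        frames = np.zeros((3, 1, 2))
        frames[:, 0, 0] = [0.0, 2.0, 40.0]
        lk = np.ones((3, 1))
        lk[2, 0] = 0.1
        rec = consensus_center(
            _tracks(frames, parts=("a", "b", "c"), likelihood=lk), px_per_cm=1.0
        )
        np.testing.assert_allclose(rec.xy[0], [1.0, 0.0])

    def test_all_missing_raises(self):
        lk = np.zeros((1, 4))
        tracks = _tracks(np.ones((1, 4, 2)), parts=("a",), likelihood=lk)
        with pytest.raises(EmptyRecordingError):
            consensus_center(tracks)

    def test_matches_bruteforce_masked_mean(self, rng):
        """Randomised tracks equal a direct per-frame, per-part loop."""
        P, n = 4, 25
        frames = np.stack(
            [rng.uniform(0, 800, size=(P, n)), rng.uniform(0, 330, size=(P, n))], axis=2
        )
        lk = rng.uniform(0, 1, size=(P, n))
        parts = tuple(f"p{i}" for i in range(P))
        rec = consensus_center(
            _tracks(frames, parts=parts, likelihood=lk),
            min_likelihood=0.5,
            px_per_cm=10.0,
            max_gap_frames=0,
        )
        for f in range(n):
            acc = [frames[p, f] for p in range(P) if lk[p, f] >= 0.5]
            if acc:
                np.testing.assert_allclose(rec.xy[f], np.mean(acc, axis=0) / 10.0, rtol=1e-12)
            else:
                assert np.isnan(rec.xy[f]).all()

    def test_permutation_invariant_in_bodypart_order(self, rng):
        P, n = 3, 10
        frames = np.stack(
            [rng.uniform(0, 800, size=(P, n)), rng.uniform(0, 330, size=(P, n))], axis=2
        )
        lk = rng.uniform(0.5, 1.0, size=(P, n))
        a = consensus_center(_tracks(frames, ("a", "b", "c"), lk), min_likelihood=0.7)
        perm = [2, 0, 1]
        b = consensus_center(
            _tracks(frames[perm], ("c", "a", "b"), lk[perm]), min_likelihood=0.7
        )
        np.testing.assert_allclose(a.xy, b.xy, rtol=1e-12)

    def test_short_gap_interpolated_long_gap_missing(self):
        n = 40
        frames = np.tile(0.5 * np.arange(n, dtype=float)[None, :, None], (1, 1, 2))
        lk = np.ones((1, n))
        lk[0, 5:8] = 0.0     # 3-frame gap -> interpolated
        lk[0, 15:30] = 0.0   # 15-frame gap -> beyond cap of 10, stays missing
        rec = consensus_center(
            _tracks(frames, ("a",), lk), px_per_cm=1.0, max_gap_frames=10
        )
        np.testing.assert_allclose(rec.xy[5:8, 0], [2.5, 3.0, 3.5])
        assert np.isnan(rec.xy[15:30]).all()


class TestSessionRoundTrip:
    def test_identity(self, tmp_path, rng, arena):
        n = 50
        xy = np.column_stack(
            [rng.uniform(0, arena.length_cm, n), rng.uniform(0, arena.width_cm, n)]
        )
        xy[7] = np.nan
        rec = SessionRecording(
            timestamps=np.arange(n) / 30.0,
            xy=xy,
            native_rate_hz=30.0,
            species_tag="Pp",
            light_condition="dim",
            arena=arena,
        )
        path = tmp_path / "s.csv"
        write_session(rec, path)
        back = read_session(path)
        np.testing.assert_allclose(back.timestamps, rec.timestamps, atol=1e-9)
        np.testing.assert_allclose(back.xy, rec.xy, atol=1e-9, equal_nan=True)
        assert back.species_tag == "Pp" and back.light_condition == "dim"
        assert back.arena == rec.arena

    def test_byte_stable_on_rewrite(self, tmp_path, rng, arena):
        n = 10_000
        xy = np.column_stack(
            [rng.uniform(0, arena.length_cm, n), rng.uniform(0, arena.width_cm, n)]
        )
        rec = SessionRecording(np.arange(n) / 30.0, xy, 30.0, arena=arena)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_session(rec, p1)
        write_session(read_session(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_version_mismatch_raises(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text("# session_csv_version: 99\ntime_s,x_cm,y_cm\n0,1,1\n")
        with pytest.raises(FormatError, match="version"):
            read_session(path)


class TestScheduleIO:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_round_trip(self, tmp_path, ext):
        sched = StimulusSchedule(kind="black_loom", onset_s=10.0, n_reps=10)
        path = tmp_path / f"sched.{ext}"
        write_schedule(sched, path)
        back = read_schedule(path)
        assert back.kind == "black_loom"
        np.testing.assert_allclose(back.onsets_s, sched.onsets_s)

    def test_point_track_monotonicity_enforced(self):
        bad = np.array([[0.0, 0.0], [1.0, 5.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="monotone"):
            StimulusSchedule(kind="cricket", point_track=bad)


@settings(derandomize=True, max_examples=25)
@given(
    n=st.integers(min_value=2, max_value=60),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_session_round_trip_randomised(tmp_path_factory, n, seed):
    rng = np.random.default_rng(seed)
    arena = ArenaConfig()
    xy = np.column_stack(
        [rng.uniform(0, arena.length_cm, n), rng.uniform(0, arena.width_cm, n)]
    )
    rec = SessionRecording(np.arange(n) / 30.0, xy, 30.0, arena=arena)
    path = tmp_path_factory.mktemp("rt") / "s.csv"
    write_session(rec, path)
    back = read_session(path)
    np.testing.assert_allclose(back.xy, rec.xy, atol=1e-9)
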