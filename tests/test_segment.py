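import numpy as np
import pytest

from kinetotrack import (
    Track,
    default_threshold,
    segment_track,
    threshold_nm_per_min,
)


def make_track(positions, visible=None):
    positions = np.asarray(positions, dtype=float)
    if visible is None:
        visible = np.ones(len(positions), dtype=bool)
    return Track(trajectory_id=0, frames=np.arange(len(positions)),
                 positions_um=positions, visible=visible)


def ramp(v_um_min, minutes, frame_interval=5.0, start=0.0):
    n = int(minutes * 60 / frame_interval)
    return start + np.arange(n) * v_um_min / 60.0 * frame_interval


class TestThreshold:
    def test_published_resolution_threshold(self):
        # one pixel (72.2 nm) per ten 5-s frames -> 86.64, printed as 86.7
        t = threshold_nm_per_min(72.2, 10, 5.0)
        assert t == pytest.approx(86.64)
        assert t == pytest.approx(86.7, abs=0.1)
        assert default_threshold(5.0) == pytest.approx(86.64)

    def test_unit_identities(self):
        assert threshold_nm_per_min(72.2, 1, 60.0) == pytest.approx(72.2)
        assert threshold_nm_per_min(100.0, 10, 6.0) == pytest.approx(100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            threshold_nm_per_min(-1.0, 10, 5.0)


class TestSegmentTrack:
    def test_constant_velocity_is_one_run(self):
        track = make_track(ramp(0.56, 30))
        seg = segment_track(track)
        assert [s.state for s in seg.segments] == ["run_plus"]
        assert seg.segments[0].velocity_um_min == pytest.approx(0.56, rel=1e-6)
        assert seg.end_on_frame is None

    def test_zero_displacement_is_one_pause(self):
        seg = segment_track(make_track(np.full(360, 2.0)))
        assert [s.state for s in seg.segments] == ["paused"]

    def test_slope_exactly_at_threshold_counts_as_moving(self):
        # 72.2 nm per 50 s == 86.64 nm/min: "less than" the threshold pauses,
        # so the boundary slope itself is moving
        track = make_track(ramp(86.64e-3, 30))
        seg = segment_track(track)
        assert [s.state for s in seg.segments] == ["run_plus"]

    def test_slope_just_below_threshold_pauses(self):
        track = make_track(ramp(80.0e-3, 30))
        seg = segment_track(track)
        assert [s.state for s in seg.segments] == ["paused"]

    def test_piecewise_run_pause_run(self):
        # 2 min at 0.6, 3 min at 0, 2 min at 0.5 µm/min
        a = ramp(0.6, 2)
        b = np.full(36, a[-1] + 0.6 / 12)
        c = ramp(0.5, 2, start=b[-1])
        track = make_track(np.concatenate([a, b, c]))
        seg = segment_track(track)
        states = [s.state for s in seg.segments]
        assert states == ["run_plus", "paused", "run_plus"]
        runs = seg.runs()
        x = track.positions_um
        lengths = [x[s.stop - 1] - x[s.start] for s in runs]
        # window-boundary tolerance: up to ~half a window of pause frames on
        # each side contributes (near-)zero displacement
        assert lengths[0] == pytest.approx(1.2, abs=0.15)
        assert lengths[1] == pytest.approx(1.0, abs=0.15)
        moving_fraction = sum(s.n_frames for s in runs) / seg.n_frames
        assert moving_fraction == pytest.approx(4 / 7, abs=2 * 10 / 84)

    def test_subwindow_bursts_merge_into_pause(self):
        # a 4-frame jiggle cannot count as a run at the stated resolution
        x = np.full(120, 1.0)
        x[60:64] = 1.0 + np.arange(4) * 0.3
        x[64:] = x[63]
        seg = segment_track(make_track(x), min_moving_frames=30)
        assert all(s.state == "paused" for s in seg.segments)

    def test_end_on_transition_and_tip_tracking(self):
        # lateral run at 0.56 to the tip parked at 2 µm, then tip tracking
        # at -0.4 µm/min
        fi = 5.0
        up = ramp(0.56, 10)
        up = up[up < 2.0]
        down = 2.0 - np.arange(360 - len(up)) * 0.4 / 60.0 * fi
        x = np.concatenate([up, down])
        mt = np.concatenate([np.full(len(up), 2.0), down])
        seg = segment_track(make_track(x), mt)
        # detection fires on the first frame within one pixel of the tip,
        # which can precede contact by one frame
        assert abs(seg.end_on_frame - len(up)) <= 1
        states = [s.state for s in seg.segments]
        assert "run_plus" in states and "tip_track" in states
        assert all(s.state != "run_plus"
                   for s in seg.segments if s.start >= seg.end_on_frame)
        tips = seg.tip_tracks()
        assert tips and tips[-1].velocity_um_min == pytest.approx(-0.4, abs=0.02)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0.005, 0.02, size=360))
        track = make_track(x)
        fractions = []
        for thr in (40.0, 86.64, 150.0, 300.0):
            seg = segment_track(track, threshold_nm_min=thr)
            fractions.append(
                sum(s.n_frames for s in seg.runs()) / seg.n_frames)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_totality_and_contiguity(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0.01, 0.03, size=200))
        seg = segment_track(make_track(x))
        assert seg.segments[0].start == 0
        assert seg.segments[-1].stop == 200
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a.stop == b.start
        assert sum(s.n_frames for s in seg.segments) == 200

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="window"):
            segment_track(make_track(np.zeros(8)))

    def test_qc_excluded_track_rejected(self):
        track = make_track(np.zeros(100))
        track.qc_excluded = True
        with pytest.raises(ValueError, match="crossed/bundled"):
            segment_track(track)

    def test_mt_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frame grid"):
            segment_track(make_track(np.zeros(100)), np.zeros(50))
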