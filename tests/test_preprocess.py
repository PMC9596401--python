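"""Telemetry preprocessing: filters, classification, synchronization."""

import numpy as np
import pandas as pd
import pytest

from shoal import (
    classify_detections,
    classify_position,
    drop_expelled,
    filter_detection_gaps,
    filter_expelled_transmitters,
    inject_transmitter_loss,
    synchronize_tracks,
)
from shoal.geometry import PondGeometry, TrialSchedule

HOUR = 3600.0


def _traj(t, x, y, fish_id=0):
    return pd.DataFrame({"fish_id": fish_id, "t": t, "x": x, "y": y})


class TestExpelledFilter:
    def test_uniform_motion_kept_with_zero_flags(self):
        t = np.arange(0, 3 * HOUR, 2.0)
        res = filter_expelled_transmitters(_traj(t, 0.1 * t, np.zeros_like(t)))
        assert not res.drop and res.flagged_windows == ()

    def test_fully_stationary_track_dropped(self):
        t = np.arange(0, 3 * HOUR, 2.0)
        res = filter_expelled_transmitters(_traj(t, np.full_like(t, 5.0), np.full_like(t, 5.0)))
        assert res.drop

    def test_noisy_swimming_track_kept(self, rng):
        t = np.arange(0, 3 * HOUR, 1.3)
        x = np.cumsum(rng.normal(0.0, 0.2, t.size))
        y = np.cumsum(rng.normal(0.0, 0.2, t.size))
        res = filter_expelled_transmitters(_traj(t, x, y))
        assert not res.drop

    def test_injected_transmitter_loss_is_caught(self, mixed_run):
        """A tag shed mid-trial leaves a low-variability tail that is flagged."""
        det = inject_transmitter_loss(mixed_run["detections"], 0, 1.5 * HOUR, seed=2)
        traj = det[det.fish_id == 0]
        res = filter_expelled_transmitters(traj)
        assert res.drop and len(res.flagged_windows) > 0
        kept, verdicts = drop_expelled(det)
        assert verdicts[0].drop
        assert 0 not in set(kept.fish_id)
        # all other fish survive the filter
        assert set(kept.fish_id) == set(range(1, 10))

    def test_loss_at_start_flags_whole_track(self, mixed_run):
        det = inject_transmitter_loss(mixed_run["detections"], 3, 0.0, seed=2)
        res = filter_expelled_transmitters(det[det.fish_id == 3])
        assert res.drop

    def test_loss_beyond_trial_end_is_noop(self, mixed_run):
        det = mixed_run["detections"]
        out = inject_transmitter_loss(det, 1, det.t.max() + 10.0)
        pd.testing.assert_frame_equal(out, det)

    def test_unknown_fish_raises(self, mixed_run):
        with pytest.raises(KeyError):
            inject_transmitter_loss(mixed_run["detections"], "nope", 10.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            filter_expelled_transmitters(_traj([0.0], [1.0], [1.0]))
        t = np.arange(0, HOUR, 2.0)
        with pytest.raises(ValueError):
            filter_expelled_transmitters(_traj(t, 0.1 * t, 0 * t), ratio=1.5)


class TestGapFilter:
    def test_small_gaps_leave_track_whole(self):
        t = np.arange(0, 100, 1.3)
        segs = filter_detection_gaps(_traj(t, t, t))
        assert len(segs) == 1 and len(segs[0]) == t.size

    def test_two_hour_gap_splits_track(self):
        t = np.concatenate([np.arange(0, 100, 2.0), np.arange(100 + 2 * HOUR, 200 + 2 * HOUR, 2.0)])
        segs = filter_detection_gaps(_traj(t, t, t))
        assert len(segs) == 2
        assert segs[0].t.max() < 200 and segs[1].t.min() > 2 * HOUR

    def test_gap_of_exactly_one_hour_retained(self):
        t = np.array([0.0, 10.0, 10.0 + HOUR, 20.0 + HOUR])
        assert len(filter_detection_gaps(_traj(t, t, t))) == 1


class TestClassification:
    @pytest.fixture()
    def geom_sched(self):
        geom = PondGeometry.default_pond("a")
        sched = TrialSchedule.regular(86400.0)
        return geom, sched

    def test_shade_centroid_by_day_and_night(self, geom_sched):
        geom, sched = geom_sched
        cx, cy = geom.shade.centroid.x, geom.shade.centroid.y
        assert classify_position(cx, cy, 10 * HOUR, geom, sched) == "shade_day"
        assert classify_position(cx, cy, 2 * HOUR, geom, sched) == "night"

    def test_far_corner_by_day_is_open(self, geom_sched):
        geom, sched = geom_sched
        assert classify_position(39.0, 24.0, 10 * HOUR, geom, sched) == "open_day"

    def test_outside_pond_rejected(self, geom_sched):
        geom, sched = geom_sched
        with pytest.raises(ValueError):
            classify_position(-1.0, 5.0, 10 * HOUR, geom, sched)

    def test_each_position_in_exactly_one_category(self, mixed_run):
        cl = mixed_run["classified"]
        assert set(cl.category.unique()) <= {"shade_day", "open_day", "night"}
        assert cl.category.notna().all()
        # night never split by location; day split agrees with the shade flag
        day = cl[cl.is_day]
        assert ((day.category == "shade_day") == day.under_shade).all()
        assert (cl[~cl.is_day].category == "night").all()


class TestSynchronization:
    def test_nearest_detection_selected(self):
        t = np.array([0.0, 1.3, 2.6, 3.9, 5.2])
        det = _traj(t, t * 10.0, np.zeros_like(t))
        fs = synchronize_tracks(det, dt=4.0)
        i = np.flatnonzero(fs.times == 4.0)[0]
        assert fs.xy[i, 0, 0] == pytest.approx(39.0)  # detection at t=3.9

    def test_equidistant_detection_assigned_to_earlier_grid_point(self):
        det = _traj(np.array([0.0, 2.0]), np.array([0.0, 7.0]), np.zeros(2))
        fs = synchronize_tracks(det, dt=4.0, t0=0.0, t1=4.0)
        assert fs.valid[0, 0] and fs.xy[0, 0, 0] == 0.0  # t=0 takes its own fix
        assert not fs.valid[1, 0]  # t=2 fix belongs to grid 0, not grid 4

    def test_stale_grid_points_marked_invalid(self):
        det = _traj(np.array([0.0, 30.0]), np.array([0.0, 1.0]), np.zeros(2))
        fs = synchronize_tracks(det, dt=4.0)
        assert fs.valid[0, 0] and not fs.valid[1, 0]

    def test_simulator_hour_gives_900_frames(self, mixed_run):
        det = mixed_run["detections"]
        hour = det[det.t < HOUR]
        fs = synchronize_tracks(hour, dt=4.0, t0=0.0, t1=HOUR - 4.0)
        assert fs.n_frames == 900
        assert fs.n_fish == 10
        assert fs.valid.mean() > 0.99

    def test_synchronization_idempotent(self, mixed_run):
        det = mixed_run["detections"]
        fs = synchronize_tracks(det[det.t < 600.0], dt=4.0)
        again = synchronize_tracks(fs.to_detections(), dt=4.0)
        np.testing.assert_array_equal(fs.valid, again.valid)
        np.testing.assert_allclose(
            fs.xy[fs.valid], again.xy[again.valid], atol=1e-12
        )
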