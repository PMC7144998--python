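"""Arena detection, segmentation, assignment, tracking and speed binning."""

import itertools

import numpy as np
import pytest

from gobysurv import simulate, tracking as trk
from gobysurv.tracking import ArenaGeometry, Blob, Trajectory


def _disc_frame(shape=(480, 640), center=(320, 240), radius=200, hi=200, lo=10):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.where(
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2, hi, lo
    )
    return img.astype(np.uint8)


class TestDetectArena:
    def test_synthetic_disc_recovered(self):
        frame = _disc_frame()
        arena = trk.detect_arena(frame)
        assert arena.center[0] == pytest.approx(320, abs=1)
        assert arena.center[1] == pytest.approx(240, abs=1)
        assert arena.radius == pytest.approx(200, abs=2)

    def test_all_black_frame_errors(self):
        with pytest.raises(ValueError, match="no region"):
            trk.detect_arena(np.zeros((100, 100), dtype=np.uint8), threshold=50)

    def test_mm_per_px_definition(self):
        arena = ArenaGeometry(center=(0, 0), radius=200)
        assert arena.mm_per_px == pytest.approx(230 / 400)


class TestSegmentBlobs:
    def test_uniform_frame_empty(self):
        arena = ArenaGeometry(center=(50, 50), radius=40)
        frame = np.full((100, 100), 128, dtype=np.uint8)
        assert trk.segment_blobs(frame, arena) == []

    def test_two_gaussian_spots_recovered(self):
        arena = ArenaGeometry(center=(120, 120), radius=100)
        centers = [(90.0, 100.0), (150.0, 140.0)]
        frames = simulate.simulate_arena_frames(
            [np.array([c]) for c in centers], arena, noise_sd=0.0
        )
        blobs = trk.segment_blobs(frames[0], arena)
        assert len(blobs) == 2
        found = sorted(b.centroid for b in blobs)
        for est, true in zip(found, sorted(centers)):
            assert est[0] == pytest.approx(true[0], abs=1)
            assert est[1] == pytest.approx(true[1], abs=1)

    def test_speck_below_min_area_excluded(self):
        arena = ArenaGeometry(center=(60, 60), radius=50)
        frame = _disc_frame((120, 120), (60, 60), 50).astype(float)
        frame[60, 60] = 0  # 1-px dark speck
        blobs = trk.segment_blobs(frame, arena, min_area=4)
        assert blobs == []
        blobs = trk.segment_blobs(frame, arena, min_area=1)
        assert len(blobs) == 1


class TestAssignBlobs:
    def test_one_fish_one_blob(self):
        assignment, imputed = trk.assign_blobs([(5.0, 5.0)], [Blob((6.0, 5.0), 10)])
        assert assignment == {0: 0} and imputed == set()

    def test_matches_brute_force_minimum(self, rng):
        """Hungarian assignment equals exhaustive permutation search."""
        for _ in range(200):
            n = int(rng.integers(2, 7))
            prev = rng.uniform(0, 100, (n, 2))
            blobs = [Blob(tuple(p), 10) for p in rng.uniform(0, 100, (n, 2))]
            assignment, imputed = trk.assign_blobs([tuple(p) for p in prev], blobs)
            assert imputed == set()
            cost = np.array(
                [[np.hypot(*(prev[i] - blobs[j].centroid)) for j in range(n)]
                 for i in range(n)]
            )
            ours = sum(cost[i, j] for i, j in assignment.items())
            best = min(
                sum(cost[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert ours == pytest.approx(best, abs=1e-9)

    def test_greedy_trap_resolved(self):
        """A layout where nearest-first matching is suboptimal."""
        prev = [(0.0, 0.0), (10.0, 0.0)]
        blobs = [Blob((4.0, 0.0), 5), Blob((-5.0, 0.0), 5)]
        assignment, _ = trk.assign_blobs(prev, blobs)
        # greedy would give fish0->blob0 (4) + fish1->blob1 (15) = 19;
        # optimum is fish0->blob1 (5) + fish1->blob0 (6) = 11
        assert assignment == {0: 1, 1: 0}

    def test_fewer_blobs_than_fish_carries_forward(self):
        prev = [(0.0, 0.0), (50.0, 0.0), (100.0, 0.0)]
        blobs = [Blob((1.0, 0.0), 5), Blob((99.0, 0.0), 5)]
        assignment, imputed = trk.assign_blobs(prev, blobs)
        assert assignment == {0: 0, 2: 1} and imputed == {1}

    def test_surplus_blobs_ignored(self):
        assignment, imputed = trk.assign_blobs(
            [(0.0, 0.0)], [Blob((20.0, 0.0), 5), Blob((1.0, 0.0), 5)]
        )
        assert assignment == {0: 1} and imputed == set()


class TestTrack:
    def test_zero_frames_gives_empty_trajectories(self):
        out = trk.track([], [(10.0, 10.0)])
        assert len(out) == 1 and len(out[0].positions) == 0

    def test_single_fish_circle(self):
        arena = ArenaGeometry(center=(120.0, 120.0), radius=100.0)
        traj = simulate.circular_trajectory(150, arena, 60.0, 1.0)
        frames = simulate.simulate_arena_frames([traj], arena, noise_sd=2.0, seed=4)
        out = trk.track(frames, [tuple(traj[0])])
        err = np.linalg.norm(out[0].positions - traj, axis=1)
        assert err.mean() < 2.0

    def test_frame_size_mismatch_errors(self):
        frames = [_disc_frame((100, 100), (50, 50), 40), np.zeros((50, 50), np.uint8)]
        with pytest.raises(ValueError, match="shape"):
            trk.track(frames, [(50.0, 50.0)])

    def test_disappearing_fish_imputed_then_reacquired(self):
        """During a gap the position is carried forward exactly (zero
        displacement); the move registers at reacquisition."""
        arena = ArenaGeometry(center=(120.0, 120.0), radius=100.0)
        path = np.column_stack([np.linspace(80, 140, 30), np.full(30, 120.0)])
        frames = simulate.simulate_arena_frames([path], arena, noise_sd=0.0)
        blank = simulate.simulate_arena_frames([], arena, noise_sd=0.0, n_frames=1)[0]
        stack = list(frames)
        for f in range(10, 15):
            stack[f] = blank  # fish vanishes
        out = trk.track(stack, [tuple(path[0])])
        tr = out[0]
        assert tr.imputed[10:15].all() and not tr.imputed[15]
        # carried forward: identical positions, zero displacement
        for f in range(10, 15):
            np.testing.assert_array_equal(tr.positions[f], tr.positions[9])
        jump = np.linalg.norm(tr.positions[15] - tr.positions[14])
        true_jump = np.linalg.norm(path[15] - path[9])
        assert jump == pytest.approx(true_jump, abs=1.0)


class TestExtractBinnedSpeeds:
    def _traj(self, positions):
        positions = np.asarray(positions, dtype=float)
        return Trajectory(0, positions, np.zeros(len(positions), dtype=bool))

    def test_stationary_fish_zero_speed(self):
        traj = self._traj(np.tile([50.0, 50.0], (4801, 1)))
        s = trk.extract_binned_speeds(traj, mm_per_px=0.575, stimulus_frame=2400)
        assert (s.before == 0).all() and (s.after == 0).all()

    def test_constant_displacement_arithmetic(self):
        # 1 px/frame at 0.575 mm/px and 20 fps -> 11.5 mm/s in every bin
        x = np.arange(4801, dtype=float)
        traj = self._traj(np.column_stack([x, np.zeros_like(x)]))
        s = trk.extract_binned_speeds(traj, mm_per_px=0.575, stimulus_frame=2400)
        np.testing.assert_allclose(s.before, 11.5)
        np.testing.assert_allclose(s.after, 11.5)

    def test_forty_plus_forty_bins(self):
        x = np.arange(4801, dtype=float)
        traj = self._traj(np.column_stack([x, x]))
        s = trk.extract_binned_speeds(traj, mm_per_px=0.5, stimulus_frame=2400)
        assert s.before.shape == (40,) and s.after.shape == (40,)

    def test_insufficient_frames_error(self):
        traj = self._traj(np.zeros((100, 2)))
        with pytest.raises(ValueError, match="span"):
            trk.extract_binned_speeds(traj, mm_per_px=0.5)

    def test_noiseless_trajectory_recovers_programmed_speed(self):
        """Binned pipeline on a programmed circular path: mean within 1%."""
        arena = ArenaGeometry(center=(120.0, 120.0), radius=100.0)
        speed_px = 0.8
        traj_xy = simulate.circular_trajectory(4801, arena, 60.0, speed_px)
        s = trk.extract_binned_speeds(
            self._traj(traj_xy), mm_per_px=arena.mm_per_px, stimulus_frame=2400
        )
        programmed = speed_px * 20.0 * arena.mm_per_px
        measured = np.concatenate([s.before, s.after]).mean()
        assert measured == pytest.approx(programmed, rel=0.01)
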