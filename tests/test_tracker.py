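import numpy as np
import pytest

from casatrack.core import BoundingBox, Detection, Point, euclidean_distance
from casatrack.simulate import SceneSpec, simulate_tracks
from casatrack.tracker import CentroidTracker, TrackerConfig, match_centroids, run

from conftest import greedy_match_oracle


def det_at(x, y, half=3.0):
    return Detection(BoundingBox(x - half, y - half, x + half, y + half), 1.0)


class TestMatchCentroids:
    def test_single_pair_within_gate(self):
        matches, ut, ui = match_centroids([(1, Point(0, 0))], [Point(3, 4)], 80)
        assert matches == [(1, 0)] and ut == [] and ui == []

    def test_beyond_gate_never_matches(self):
        matches, ut, ui = match_centroids([(1, Point(0, 0))], [Point(100, 0)], 80)
        assert matches == [] and ut == [1] and ui == [0]

    def test_distance_exactly_at_gate_matches(self):
        matches, _, _ = match_centroids([(0, Point(0, 0))], [Point(80, 0)], 80)
        assert matches == [(0, 0)]

    def test_empty_inputs(self):
        assert match_centroids([], [Point(1, 1)], 80) == ([], [], [0])
        assert match_centroids([(4, Point(1, 1))], [], 80) == ([], [4], [])

    def test_greedy_prefers_globally_smallest_distance(self):
        existing = [(0, Point(0, 0)), (1, Point(10, 0))]
        incoming = [Point(9, 0), Point(2, 0)]
        matches, _, _ = match_centroids(existing, incoming, 80)
        # (1 -> 9,0) at distance 1 is the global minimum and goes first
        assert sorted(matches) == [(0, 1), (1, 0)]

    def test_agrees_with_independent_greedy_oracle(self, rng):
        for _ in range(200):
            n_t = int(rng.integers(0, 6))
            n_i = int(rng.integers(0, 6))
            gate = float(rng.uniform(10, 120))
            existing = [
                (int(tid), Point(*rng.uniform(0, 200, 2)))
                for tid in rng.choice(50, size=n_t, replace=False)
            ]
            incoming = [Point(*rng.uniform(0, 200, 2)) for _ in range(n_i)]
            got, _, _ = match_centroids(existing, incoming, gate)
            assert got == greedy_match_oracle(existing, incoming, gate)

    def test_optimal_mode_is_a_valid_gated_matching(self, rng):
        existing = [(i, Point(*rng.uniform(0, 100, 2))) for i in range(5)]
        incoming = [Point(*rng.uniform(0, 100, 2)) for _ in range(5)]
        matches, _, _ = match_centroids(existing, incoming, 60, matching="optimal")
        pos = dict(existing)
        assert len({t for t, _ in matches}) == len(matches)
        assert len({c for _, c in matches}) == len(matches)
        for tid, c in matches:
            assert euclidean_distance(pos[tid], incoming[c]) <= 60


class TestStep:
    def test_first_frame_registers_all(self):
        tracker = CentroidTracker()
        st = tracker.step([det_at(10, 10), det_at(50, 50), det_at(90, 90)], 0)
        assert sorted(st.tracks) == [0, 1, 2]
        assert all(t.total_distance_px == 0.0 for t in st.tracks.values())

    def test_matched_track_accumulates_distance(self):
        tracker = CentroidTracker()
        tracker.step([det_at(100, 100)], 0)
        st = tracker.step([det_at(130, 140)], 1)
        assert sorted(st.tracks) == [0]
        assert st.tracks[0].total_distance_px == pytest.approx(50.0)

    def test_non_monotonic_frame_index_rejected(self):
        tracker = CentroidTracker()
        tracker.step([det_at(10, 10)], 5)
        with pytest.raises(ValueError):
            tracker.step([det_at(11, 11)], 5)

    def test_unmatched_track_retires_after_tolerance(self):
        tracker = CentroidTracker(TrackerConfig(max_missed_frames=1))
        tracker.step([det_at(10, 10)], 0)
        tracker.step([], 1)
        assert 0 in tracker.state.tracks  # one miss tolerated
        st = tracker.step([], 2)
        assert 0 not in st.tracks and 0 in st.retired
        assert st.retired[0].n_points == 1  # history preserved

    def test_rematch_within_tolerance_resets_miss_counter(self):
        tracker = CentroidTracker(TrackerConfig(max_missed_frames=2))
        tracker.step([det_at(10, 10)], 0)
        tracker.step([], 1)
        st = tracker.step([det_at(12, 10)], 2)
        assert st.tracks[0].missed_frames == 0
        assert st.tracks[0].n_points == 2

    def test_scene_cut_reset(self):
        cfg = TrackerConfig(reset_fraction=0.5)
        tracker = CentroidTracker(cfg)
        tracker.step([det_at(10, 10), det_at(100, 100), det_at(200, 200)], 0)
        # all three jump far beyond the gate: a scene cut
        st = tracker.step([det_at(400, 400), det_at(500, 100), det_at(300, 30)], 1)
        assert sorted(st.retired) == [0, 1, 2]
        assert sorted(st.tracks) == [3, 4, 5]


class TestRun:
    def test_no_frames(self):
        assert run([]) == []

    def test_single_frame_single_point_tracks(self):
        tracks = run([[det_at(10, 10), det_at(60, 60), det_at(110, 110), det_at(160, 160)]])
        assert len(tracks) == 4
        assert all(t.n_points == 1 for t in tracks)

    def test_single_moving_object_polyline_identity(self, rng):
        pos = np.array([100.0, 100.0])
        frames, truth = [], [pos.copy()]
        for _ in range(40):
            pos = pos + rng.uniform(-10, 10, 2)
            frames.append([det_at(*pos)])
            truth.append(pos.copy())
        (track,) = run([[det_at(100, 100)]] + frames)
        expected = sum(
            np.hypot(*(b - a)) for a, b in zip(truth, truth[1:])
        )
        assert track.total_distance_px == pytest.approx(expected, rel=1e-9)

    def test_track_count_never_decreases_and_histories_survive(self):
        frames = [[det_at(10, 10)], [], [], [], [], [], [], [], [det_at(300, 300)]]
        tracks = run(frames, TrackerConfig(max_missed_frames=2))
        assert len(tracks) == 2  # retired track still reported
        assert {t.track_id for t in tracks} == {0, 1}

    def test_detection_conservation(self, rng):
        # every processed detection is either matched or registered
        frames = []
        for _ in range(30):
            k = int(rng.integers(0, 8))
            frames.append([det_at(*rng.uniform(10, 600, 2)) for _ in range(k)])
        tracker = CentroidTracker()
        for i, dets in enumerate(frames):
            tracker.step(dets, i)
        st = tracker.state
        total = sum(len(f) for f in frames)
        assert st.n_matched + st.n_registered == st.n_detections_processed == total
        assert sum(t.n_points for t in st.all_tracks()) == total

    def test_clean_simulated_scene_tracked_with_full_identity(self):
        spec = SceneSpec(n_heads=10, duration_s=0.5, seed=11, jitter_sigma_px=0.0)
        gt = simulate_tracks(spec)
        tracks = run(gt.detections())
        assert len(tracks) == 10
        # each track's trajectory must coincide with exactly one head's truth
        truth = {
            h.head_id: [(f, p.x, p.y) for f, p in h.trajectory] for h in gt.heads
        }
        for t in tracks:
            got = [(f, round(p.x, 6), round(p.y, 6)) for f, p in t.centroids]
            matched = [
                hid
                for hid, traj in truth.items()
                if len(traj) == len(got)
                and all(
                    f1 == f2 and abs(x1 - x2) < 1e-6 and abs(y1 - y2) < 1e-6
                    for (f1, x1, y1), (f2, x2, y2) in zip(traj, got)
                )
            ]
            assert len(matched) == 1
            del truth[matched[0]]
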