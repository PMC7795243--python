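"""Centroid tracking: identity assignment across frames by gated
minimum-Euclidean-distance matching.

Each frame's detections are reduced to their box centroids; centroids are
associated to existing tracks greedily, smallest pairwise distance first,
subject to a maximum association gate (80 px by default — roughly the
largest plausible per-frame displacement of a sperm head at 50 fps).
Unmatched centroids register new tracks; tracks unmatched for more than
``max_missed_frames`` consecutive frames are retired but keep their full
history, which downstream vitality assessment still counts.

No motion model is used: association is nearest-neighbor on the last
recorded position only. Identity swaps between two heads that cross within
the gate are therefore possible; path lengths (hence speeds) are barely
affected by a swap, which is why the simple scheme suffices for
vitality-style statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Detection, Point, Track, compute_centroid, euclidean_distance

__all__ = ["TrackerConfig", "TrackerState", "CentroidTracker", "match_centroids", "run"]


@dataclass
class TrackerConfig:
    """Association parameters.

    gate_px
        Maximum association distance in pixels; a centroid farther than this
        from every track can never extend one. Default 80.
    max_missed_frames
        Consecutive unmatched frames tolerated before a track is retired.
        Default 5 (0.1 s of occlusion at 50 fps).
    matching
        "greedy" (smallest-distance-first, the default) or "optimal"
        (minimum-total-distance assignment via the Hungarian algorithm).
    reset_fraction
        Optional scene-cut guard: if more than this fraction of live tracks
        lose their match in a single frame, all tracks are retired and the
        frame's centroids re-register. ``None`` (default) disables it.
    """

    gate_px: float = 80.0
    max_missed_frames: int = 5
    matching: str = "greedy"
    reset_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.gate_px <= 0:
            raise ValueError(f"gate_px must be > 0, got {self.gate_px}")
        if self.max_missed_frames < 0:
            raise ValueError("max_missed_frames must be >= 0")
        if self.matching not in ("greedy", "optimal"):
            raise ValueError("matching must be 'greedy' or 'optimal'")


def match_centroids(
    existing: Sequence[tuple[int, Point]],
    incoming: Sequence[Point],
    gate_px: float,
    matching: str = "greedy",
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate incoming centroids to existing tracks within a distance gate.

    Greedy mode repeatedly takes the smallest remaining pairwise distance
    <= ``gate_px``, assigns that (track, centroid) pair and removes both;
    ties break on (lower track_id, lower incoming index). Optimal mode
    solves the gated minimum-total-distance assignment instead.

    Returns ``(matches, unmatched_track_ids, unmatched_incoming_indices)``
    where matches are ``(track_id, incoming_index)`` pairs. No pair at
    distance > gate is ever produced; each side is matched at most once.
    """
    if gate_px <= 0:
        raise ValueError(f"gate_px must be > 0, got {gate_px}")
    if not existing or not incoming:
        return [], [tid for tid, _ in existing], list(range(len(incoming)))

    track_ids = [tid for tid, _ in existing]
    dist = np.array(
        [[euclidean_distance(p, q) for q in incoming] for _, p in existing]
    )

    matches: list[tuple[int, int]] = []
    if matching == "optimal":
        from scipy.optimize import linear_sum_assignment

        cost = np.where(dist <= gate_px, dist, 1e12)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if dist[r, c] <= gate_px:
                matches.append((track_ids[r], int(c)))
    else:
        pairs = [
            (dist[r, c], track_ids[r], c, r)
            for r in range(len(existing))
            for c in range(len(incoming))
            if dist[r, c] <= gate_px
        ]
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        used_rows: set[int] = set()
        used_cols: set[int] = set()
        for _, tid, c, r in pairs:
            if r in used_rows or c in used_cols:
                continue
            matches.append((tid, c))
            used_rows.add(r)
            used_cols.add(c)

    matched_tids = {tid for tid, _ in matches}
    matched_cols = {c for _, c in matches}
    unmatched_tracks = [tid for tid in track_ids if tid not in matched_tids]
    unmatched_incoming = [c for c in range(len(incoming)) if c not in matched_cols]
    return matches, unmatched_tracks, unmatched_incoming


@dataclass
class TrackerState:
    """Mutable tracker state: live tracks, retired tracks, id counter."""

    config: TrackerConfig = field(default_factory=TrackerConfig)
    tracks: dict[int, Track] = field(default_factory=dict)
    retired: dict[int, Track] = field(default_factory=dict)
    next_id: int = 0
    last_frame_index: int | None = None
    # running conservation counters: matches + registrations == detections seen
    n_detections_processed: int = 0
    n_matched: int = 0
    n_registered: int = 0

    def all_tracks(self) -> list[Track]:
        """Live and retired tracks, ordered by id."""
        merged = {**self.retired, **self.tracks}
        return [merged[k] for k in sorted(merged)]


class CentroidTracker:
    """Stateful per-frame tracker; feed frames in order via :meth:`step`."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.state = TrackerState(config=config or TrackerConfig())

    def _register(self, frame_index: int, point: Point) -> None:
        st = self.state
        track = Track(track_id=st.next_id)
        track.append(frame_index, point)
        st.tracks[st.next_id] = track
        st.next_id += 1
        st.n_registered += 1

    def step(self, detections: Sequence[Detection], frame_index: int) -> TrackerState:
        """Process one frame of (already score-filtered) detections."""
        st = self.state
        cfg = st.config
        if st.last_frame_index is not None and frame_index <= st.last_frame_index:
            raise ValueError(
                f"frame_index {frame_index} not strictly greater than "
                f"last processed {st.last_frame_index}"
            )
        st.last_frame_index = frame_index
        centroids = [compute_centroid(d.box) for d in detections]
        st.n_detections_processed += len(centroids)

        if not st.tracks:
            for p in centroids:
                self._register(frame_index, p)
            return st

        existing = [(tid, st.tracks[tid].last_point) for tid in sorted(st.tracks)]
        matches, unmatched_tracks, unmatched_incoming = match_centroids(
            existing, centroids, cfg.gate_px, cfg.matching
        )

        if (
            cfg.reset_fraction is not None
            and len(existing) > 0
            and len(unmatched_tracks) / len(existing) > cfg.reset_fraction
        ):
            # scene cut: retire everything, re-register the whole frame
            for tid in list(st.tracks):
                st.retired[tid] = st.tracks.pop(tid)
            for p in centroids:
                self._register(frame_index, p)
            return st

        for tid, c in matches:
            # gate is a hard guarantee, not a heuristic
            assert (
                euclidean_distance(st.tracks[tid].last_point, centroids[c])
                <= cfg.gate_px
            )
            st.tracks[tid].append(frame_index, centroids[c])
            st.tracks[tid].missed_frames = 0
        st.n_matched += len(matches)

        for c in unmatched_incoming:
            self._register(frame_index, centroids[c])

        for tid in unmatched_tracks:
            track = st.tracks[tid]
            track.missed_frames += 1
            if track.missed_frames > cfg.max_missed_frames:
                st.retired[tid] = st.tracks.pop(tid)
        return st


def run(
    frames_detections: Sequence[Sequence[Detection]],
    config: TrackerConfig | None = None,
) -> list[Track]:
    """Track a whole ordered sequence of per-frame detection lists.

    Returns every track created during the run — live and retired — with
    full centroid histories, ordered by track id. Deterministic for fixed
    input and config.
    """
    tracker = CentroidTracker(config)
    for frame_index, dets in enumerate(frames_detections):
        tracker.step(dets, frame_index)
    st = tracker.state
    assert st.n_matched + st.n_registered == st.n_detections_processed
    return st.all_tracks()
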