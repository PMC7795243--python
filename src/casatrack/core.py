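"""Domain types and elementary geometry shared by every pipeline stage.

Coordinate convention: continuous pixel coordinates, origin at the top-left
corner of the frame, x increasing rightward and y increasing downward (the
usual image-array convention). Bounding boxes are half-open on their max
edges, so a box spanning one rendered pixel at (r, c) is
(c, r, c + 1, r + 1). Sub-pixel positions are allowed everywhere; integer
quantisation only happens at rendering and VOC-XML export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "BoundingBox",
    "Detection",
    "Point",
    "Track",
    "compute_centroid",
    "euclidean_distance",
]

SPERM_HEAD_CLASS = 1
"""Single object class of the detector: a sperm head (head + neck, no tail)."""


class Point(NamedTuple):
    """A continuous 2-D pixel coordinate."""

    x: float
    y: float


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in absolute pixel coordinates, half-open max edges."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if min(vals) < 0:
            raise ValueError(f"box coordinates must be >= 0, got {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: need x_min < x_max and y_min < y_max, got {vals}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy
        )


@dataclass(frozen=True)
class Detection:
    """One candidate sperm head in one frame: a box plus a confidence score."""

    box: BoundingBox
    score: float
    class_id: int = SPERM_HEAD_CLASS

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class Track:
    """Identity-resolved centroid history of one sperm head across frames.

    ``total_distance_px`` is the cumulative Euclidean path length of the
    centroid polyline; it is maintained incrementally by the tracker and
    always equals the sum of consecutive-centroid distances.
    """

    track_id: int
    centroids: list[tuple[int, Point]] = field(default_factory=list)
    total_distance_px: float = 0.0
    missed_frames: int = 0

    @property
    def n_points(self) -> int:
        return len(self.centroids)

    @property
    def first_frame(self) -> int:
        return self.centroids[0][0]

    @property
    def last_frame(self) -> int:
        return self.centroids[-1][0]

    @property
    def last_point(self) -> Point:
        return self.centroids[-1][1]

    def append(self, frame_index: int, point: Point) -> None:
        """Append a centroid, accumulating the step distance.

        Frame indices must be strictly increasing within a track.
        """
        if self.centroids:
            if frame_index <= self.last_frame:
                raise ValueError(
                    f"track {self.track_id}: frame {frame_index} not after "
                    f"{self.last_frame}"
                )
            self.total_distance_px += euclidean_distance(self.last_point, point)
        self.centroids.append((frame_index, Point(*point)))

    def path_length(self) -> float:
        """Recompute the polyline length from scratch (cross-check helper)."""
        pts = [p for _, p in self.centroids]
        return sum(euclidean_distance(a, b) for a, b in zip(pts, pts[1:]))


def compute_centroid(box: BoundingBox) -> Point:
    """Center of a bounding box: the average of its start and end coordinates."""
    return Point((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


def euclidean_distance(p: Point, q: Point) -> float:
    """Euclidean distance d(p, q) = sqrt((qx-px)^2 + (qy-py)^2), in pixels."""
    return math.hypot(q[0] - p[0], q[1] - p[1])
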