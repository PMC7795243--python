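"""Physical calibration, per-track speed, viability classification and
sample-level vitality.

The decision layer works in physical-ish units: the microscope calibration
(0.66 µm per pixel at 400x, 50 fps for the source videos) converts the
clinical viability criterion — a viable sperm swims at least 34.5 µm/s —
into a pixel-per-second cut, floored to 52 px/s. A track's mean path speed
(cumulative centroid path length over its lifetime) is compared against
that cut; the sample's vitality is the percentage of classified-viable
tracks among trackable ("live") ones, and a sample whose vitality exceeds
58% is judged suitable for insemination.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

from .core import Track

__all__ = [
    "Calibration",
    "VitalityReport",
    "speed_threshold_px_s",
    "track_speed",
    "classify_viable",
    "compute_vitality",
    "assess_sample",
]

SUITABILITY_THRESHOLD_PCT = 58.0
"""Minimum sample vitality (exclusive) for an insemination-suitable verdict."""


@dataclass(frozen=True)
class Calibration:
    """Physical constants mapping pixels and frames to micrometers and seconds.

    um_per_px
        Micrometer size of one pixel in the video frames (0.66 µm at the
        source videos' 400x magnification).
    fps
        Frame rate of the video, frames per second.
    viable_speed_um_s
        Minimum swimming speed of a viable sperm, µm/s.
    magnification
        Informational only; plays no role in any computation.
    """

    um_per_px: float = 0.66
    fps: float = 50.0
    viable_speed_um_s: float = 34.5
    magnification: float = 400.0

    def __post_init__(self) -> None:
        for name in ("um_per_px", "fps", "viable_speed_um_s", "magnification"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"Calibration.{name} must be strictly positive, got {v}")


@dataclass
class VitalityReport:
    """Sample-level vitality summary.

    n_found counts all tracks; n_live those trackable across >= 2 frames
    (speed defined); n_viable those at or above the speed cut. vitality_pct
    is 100 * n_viable / n_live in count mode (0 when nothing is live), or
    the viable share of total path distance in distance mode.
    """

    n_found: int
    n_live: int
    n_viable: int
    vitality_pct: float
    suitable: bool
    suitability_threshold_pct: float = SUITABILITY_THRESHOLD_PCT
    mode: str = "count"

    def __post_init__(self) -> None:
        if not (0 <= self.n_viable <= self.n_live <= self.n_found):
            raise ValueError(
                f"need 0 <= viable <= live <= found, got "
                f"{self.n_viable}/{self.n_live}/{self.n_found}"
            )
        if not (0.0 <= self.vitality_pct <= 100.0):
            raise ValueError(f"vitality_pct must be in [0, 100], got {self.vitality_pct}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> dict:
        """One record mirroring a results-table row (counts + rounded %)."""
        return {
            "found": self.n_found,
            "live": self.n_live,
            "viable": self.n_viable,
            "estimated_viability_pct": int(round(self.vitality_pct)),
            "suitable": self.suitable,
        }


def speed_threshold_px_s(cal: Calibration) -> int:
    """Viability speed cut in pixels per second.

    Floor of the µm-to-px conversion: 34.5 µm/s over 0.66 µm/px is
    52.27... px/s, reported and applied as 52 px/s. The floor (rather than
    rounding) matches how the printed cut is derived from the calibration.
    """
    return int(cal.viable_speed_um_s / cal.um_per_px)


def track_speed(track: Track, cal: Calibration) -> float | None:
    """Mean path speed of a track in px/s, or None for single-point tracks.

    Speed = total path length / lifetime, lifetime = (last - first frame)/fps.
    A track seen in only one frame has no defined speed; batch callers treat
    it as non-motile rather than erroring.
    """
    if track.n_points < 2:
        return None
    duration_s = (track.last_frame - track.first_frame) / cal.fps
    return track.total_distance_px / duration_s


def classify_viable(
    speed_px_s: float, threshold_px_s: float, inclusive: bool = True
) -> bool:
    """Viable iff the speed meets the cut (>= by default; > if inclusive=False)."""
    if speed_px_s < 0:
        raise ValueError(f"speed must be >= 0, got {speed_px_s}")
    return speed_px_s >= threshold_px_s if inclusive else speed_px_s > threshold_px_s


def compute_vitality(
    tracks: Sequence[Track],
    cal: Calibration | None = None,
    mode: str = "count",
    suitability_threshold_pct: float = SUITABILITY_THRESHOLD_PCT,
) -> VitalityReport:
    """Sample vitality from one segment's tracks.

    count mode (primary): vitality = 100 * n_viable / n_live.
    distance mode: vitality = 100 * (path distance of viable tracks) /
    (path distance of all live tracks) — the literal distance-weighted
    reading of the vitality ratio.
    """
    if mode not in ("count", "distance"):
        raise ValueError(f"mode must be 'count' or 'distance', got {mode!r}")
    cal = cal or Calibration()
    threshold = speed_threshold_px_s(cal)

    n_found = len(tracks)
    live = [(t, s) for t in tracks if (s := track_speed(t, cal)) is not None]
    n_live = len(live)
    viable = [(t, s) for t, s in live if classify_viable(s, threshold)]
    n_viable = len(viable)

    if n_live == 0:
        vitality = 0.0
    elif mode == "count":
        vitality = 100.0 * n_viable / n_live
    else:
        total_dist = sum(t.total_distance_px for t, _ in live)
        vitality = (
            100.0 * sum(t.total_distance_px for t, _ in viable) / total_dist
            if total_dist > 0
            else 0.0
        )

    return VitalityReport(
        n_found=n_found,
        n_live=n_live,
        n_viable=n_viable,
        vitality_pct=vitality,
        suitable=vitality > suitability_threshold_pct,
        suitability_threshold_pct=suitability_threshold_pct,
        mode=mode,
    )


def assess_sample(report: VitalityReport) -> bool:
    """Suitability verdict: vitality strictly greater than the 58% threshold."""
    return report.vitality_pct > report.suitability_threshold_pct
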