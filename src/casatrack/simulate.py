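"""Synthetic sperm-video generator with exact ground truth.

Produces scenes that emulate the source videos' geometry (640x480 px,
50 fps, a few to ~175 heads per frame) and the two speed regimes reported
for tracked heads (motile mean ~162.5 px/s, non-motile ~33.35 px/s at
0.66 µm/px). Motile heads follow a constant-speed persistent-direction
random walk (per-frame step = speed/fps plus heading diffusion); non-motile
heads take uncorrelated small steps (jitter-like wandering). Per-head speeds
are drawn from truncated normal distributions whose supports sit strictly
on the correct side of the 52 px/s viability cut, so the ground-truth
motion class of every head agrees with its realized path speed — a
"non-motile" head swimming above the viability criterion would contradict
the class definition.

Everything is driven by a single integer seed; identical spec + seed gives
bit-identical trajectories and rendered frames.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import BoundingBox, Detection, Point
from .io import write_detection_table, write_frames, write_voc_xml

__all__ = [
    "SceneSpec",
    "HeadTruth",
    "GroundTruth",
    "simulate_tracks",
    "render_frames",
    "export_ground_truth",
    "perturb_detections",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Speeds are in µm/s and converted with ``um_per_px``; head-count and
    frame-geometry defaults follow the source videos (mean ~41 heads per
    640x480 frame at 50 fps). ``motile_fraction`` defaults to 0.85, in the
    range of experimental viability values of clinical samples deemed
    analyzable. Speed distributions are truncated normals: motile
    107 ± 25 µm/s on [45, 250] (mean 162.5 px/s), non-motile 22 ± 5 µm/s on
    [2, 30] (mean 33.35 px/s).
    """

    width: int = 640
    height: int = 480
    fps: float = 50.0
    duration_s: float = 1.0
    n_heads: int = 41
    motile_fraction: float = 0.85
    um_per_px: float = 0.66
    motile_speed_um_s: tuple[float, float] = (107.0, 25.0)   # mean, sd
    motile_speed_bounds_um_s: tuple[float, float] = (45.0, 250.0)
    nonmotile_speed_um_s: tuple[float, float] = (22.0, 5.0)
    nonmotile_speed_bounds_um_s: tuple[float, float] = (2.0, 30.0)
    heading_sigma_rad: float = 0.15
    jitter_sigma_px: float = 0.2
    head_axes_px: tuple[float, float] = (3.5, 2.3)  # semi-axes: along/across heading
    background_level: float = 30.0
    head_intensity: float = 200.0
    noise_sigma: float = 4.0
    occlusion_rate: float = 0.0
    boundary: str = "reflect"  # "reflect" or "none" (unbounded)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame must have positive area")
        if self.n_heads < 0:
            raise ValueError("n_heads must be >= 0")
        if not (0.0 <= self.motile_fraction <= 1.0):
            raise ValueError(f"motile_fraction must be in [0, 1], got {self.motile_fraction}")
        if not (0.0 <= self.occlusion_rate < 1.0):
            raise ValueError("occlusion_rate must be in [0, 1)")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.boundary not in ("reflect", "none"):
            raise ValueError("boundary must be 'reflect' or 'none'")
        if min(self.head_axes_px) <= 0:
            raise ValueError("head axes must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class HeadTruth:
    """Ground truth for one head: class, trajectory and per-frame boxes."""

    head_id: int
    motile: bool
    speed_um_s: float
    trajectory: list[tuple[int, Point]] = field(default_factory=list)
    boxes: list[tuple[int, BoundingBox]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Full specification of a simulated scene, the simulation oracle."""

    spec: SceneSpec
    heads: list[HeadTruth]

    @property
    def vitality_pct(self) -> float:
        """Class-based vitality: motile share of heads, count mode."""
        if not self.heads:
            return 0.0
        return 100.0 * sum(h.motile for h in self.heads) / len(self.heads)

    def detections(self) -> list[list[Detection]]:
        """Perfect per-frame detections (ground-truth boxes, score 1)."""
        out: list[list[Detection]] = [[] for _ in range(self.spec.n_frames)]
        for head in self.heads:
            for frame, box in head.boxes:
                out[frame].append(Detection(box, 1.0))
        return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws by rejection (supports are wide; cheap)."""
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draws = rng.normal(mean, sd, remaining.size)
        ok = (draws >= lo) & (draws <= hi)
        out[remaining[ok]] = draws[ok]
        remaining = remaining[~ok]
    return out


def _head_box(x: float, y: float, heading: float, axes: tuple[float, float]) -> BoundingBox:
    """Axis-aligned bounding box of an ellipse at (x, y) rotated to heading."""
    a, b = axes
    c, s = math.cos(heading), math.sin(heading)
    hx = math.sqrt((a * c) ** 2 + (b * s) ** 2)
    hy = math.sqrt((a * s) ** 2 + (b * c) ** 2)
    return BoundingBox(
        max(x - hx, 0.0), max(y - hy, 0.0), max(x + hx, 1e-6), max(y + hy, 1e-6)
    )


def simulate_tracks(spec: SceneSpec) -> GroundTruth:
    """Simulate ground-truth trajectories for one scene.

    The first ``round(n_heads * motile_fraction)`` heads are motile, so the
    scene's class composition is exact, not binomial. Reflective boundaries
    (the default) keep heads inside the field, preserving step lengths and
    hence path speeds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_heads
    n_motile = int(round(n * spec.motile_fraction))
    dt = 1.0 / spec.fps
    margin = max(spec.head_axes_px) + 1.0

    speeds_px = np.empty(n)
    if n_motile:
        m, sd = spec.motile_speed_um_s
        lo, hi = spec.motile_speed_bounds_um_s
        speeds_px[:n_motile] = _truncated_normal(rng, m, sd, lo, hi, n_motile) / spec.um_per_px
    if n - n_motile:
        m, sd = spec.nonmotile_speed_um_s
        lo, hi = spec.nonmotile_speed_bounds_um_s
        speeds_px[n_motile:] = _truncated_normal(rng, m, sd, lo, hi, n - n_motile) / spec.um_per_px

    x = rng.uniform(margin, spec.width - margin, n)
    y = rng.uniform(margin, spec.height - margin, n)
    heading = rng.uniform(0.0, 2.0 * math.pi, n)

    heads = [
        HeadTruth(head_id=i, motile=i < n_motile, speed_um_s=speeds_px[i] * spec.um_per_px)
        for i in range(n)
    ]

    for frame in range(spec.n_frames):
        for i, head in enumerate(heads):
            head.trajectory.append((frame, Point(float(x[i]), float(y[i]))))
            head.boxes.append(
                (frame, _head_box(float(x[i]), float(y[i]), float(heading[i]), spec.head_axes_px))
            )
        if frame == spec.n_frames - 1:
            break
        # advance one time step
        if n_motile:
            heading[:n_motile] += rng.normal(0.0, spec.heading_sigma_rad, n_motile)
        if n - n_motile:
            heading[n_motile:] = rng.uniform(0.0, 2.0 * math.pi, n - n_motile)
        step = speeds_px * dt
        dx = step * np.cos(heading) + rng.normal(0.0, spec.jitter_sigma_px, n)
        dy = step * np.sin(heading) + rng.normal(0.0, spec.jitter_sigma_px, n)
        x += dx
        y += dy
        if spec.boundary == "reflect":
            # billiard reflection: mirror the overshoot and flip the heading
            # component, so heads bounce off walls instead of sticking to them
            lo = margin
            hi_x = spec.width - margin
            bounced = (x > hi_x) | (x < lo)
            x[x > hi_x] = 2 * hi_x - x[x > hi_x]
            x[x < lo] = 2 * lo - x[x < lo]
            heading[bounced] = math.pi - heading[bounced]
            hi_y = spec.height - margin
            bounced = (y > hi_y) | (y < lo)
            y[y > hi_y] = 2 * hi_y - y[y > hi_y]
            y[y < lo] = 2 * lo - y[y < lo]
            heading[bounced] = -heading[bounced]
    return GroundTruth(spec=spec, heads=heads)


def render_frames(gt: GroundTruth, spec: SceneSpec | None = None) -> list[np.ndarray]:
    """Render the scene: bright head ellipses on a noisy dark background.

    Heads are filled rotated ellipses at ``head_intensity`` over a
    ``background_level`` field with additive Gaussian noise of sd
    ``noise_sigma``; heads are clipped at the frame border (so a head
    half outside the field renders as a partial blob). uint8 output,
    bit-identical for identical spec + seed.
    """
    spec = spec or gt.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    a, b = spec.head_axes_px
    frames = []
    for frame_idx in range(spec.n_frames):
        img = np.full((spec.height, spec.width), spec.background_level, dtype=float)
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
        for head in gt.heads:
            frame, p = head.trajectory[frame_idx]
            # heading from trajectory tangent (fallback: x-axis)
            if frame_idx + 1 < len(head.trajectory):
                q = head.trajectory[frame_idx + 1][1]
                theta = math.atan2(q.y - p.y, q.x - p.x)
            elif frame_idx > 0:
                q = head.trajectory[frame_idx - 1][1]
                theta = math.atan2(p.y - q.y, p.x - q.x)
            else:
                theta = 0.0
            r = math.ceil(max(a, b)) + 1
            y0, y1 = int(p.y) - r, int(p.y) + r + 1
            x0, x1 = int(p.x) - r, int(p.x) + r + 1
            yy, xx = np.mgrid[max(y0, 0) : min(y1, spec.height), max(x0, 0) : min(x1, spec.width)]
            if yy.size == 0:
                continue
            dx = xx + 0.5 - p.x
            dy = yy + 0.5 - p.y
            c, s = math.cos(theta), math.sin(theta)
            u = (dx * c + dy * s) / a
            v = (-dx * s + dy * c) / b
            inside = u * u + v * v <= 1.0
            sub = img[max(y0, 0) : min(y1, spec.height), max(x0, 0) : min(x1, spec.width)]
            sub[inside] = spec.head_intensity
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
    return frames


def perturb_detections(
    gt: GroundTruth,
    sigma_px: float = 0.3,
    miss_rate: float = 0.02,
    fp_rate_per_frame: float = 0.2,
    seed: int = 0,
) -> list[list[Detection]]:
    """Detection-noise model applied to ground-truth boxes.

    Emulates what an imperfect detector delivers: sub-pixel localization
    jitter (each box translated by N(0, sigma_px^2) per axis), a fraction of
    missed detections (dropped per head per frame, also covering transient
    occlusion), and optional spurious false-positive boxes. Scores of true
    detections are 1.0; false positives score 0.9 (above the default gate,
    as confident detector mistakes are the damaging ones).
    """
    spec = gt.spec
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out: list[list[Detection]] = [[] for _ in range(spec.n_frames)]
    drop = max(miss_rate + spec.occlusion_rate, 0.0)
    for head in gt.heads:
        for frame, box in head.boxes:
            if drop > 0 and rng.random() < drop:
                continue
            ddx, ddy = rng.normal(0.0, sigma_px, 2)
            try:
                out[frame].append(Detection(box.translate(ddx, ddy), 1.0))
            except ValueError:
                out[frame].append(Detection(box, 1.0))
    if fp_rate_per_frame > 0:
        a, b = spec.head_axes_px
        for frame in range(spec.n_frames):
            for _ in range(rng.poisson(fp_rate_per_frame)):
                cx = rng.uniform(a, spec.width - a)
                cy = rng.uniform(b, spec.height - b)
                out[frame].append(
                    Detection(BoundingBox(cx - a, cy - b, cx + a, cy + b), 0.9)
                )
    return out


def export_ground_truth(
    gt: GroundTruth, spec: SceneSpec | None = None, out_dir: str | os.PathLike = "."
) -> dict[str, Path]:
    """Write the scene to disk: frames, VOC XML, detection and track tables.

    Layout: ``frames/frame_#####.png``, ``annotations/frame_#####.xml``,
    ``detections.csv``, ``tracks.csv``, ``scene.json`` (spec + class truth +
    vitality). Everything is re-importable by the io and detect modules.
    """
    spec = spec or gt.spec
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        frames = render_frames(gt, spec)
        frame_paths = write_frames(out_dir / "frames", frames)

        ann_dir = out_dir / "annotations"
        ann_dir.mkdir(exist_ok=True)
        per_frame_boxes: list[list[BoundingBox]] = [[] for _ in range(spec.n_frames)]
        for head in gt.heads:
            for frame, box in head.boxes:
                per_frame_boxes[frame].append(box)
        for i, boxes in enumerate(per_frame_boxes):
            write_voc_xml(
                ann_dir / f"frame_{i:05d}.xml",
                frame_paths[i].name,
                (spec.width, spec.height),
                boxes,
            )

        det_path = out_dir / "detections.csv"
        write_detection_table(det_path, gt.detections(), coords="absolute")

        track_path = out_dir / "tracks.csv"
        rows = ["head_id,frame,x,y"]
        for head in gt.heads:
            for frame, p in head.trajectory:
                rows.append(f"{head.head_id},{frame},{p.x},{p.y}")
        track_path.write_text("\n".join(rows) + "\n")

        scene_path = out_dir / "scene.json"
        scene = {
            "spec": asdict(spec),
            "vitality_pct": gt.vitality_pct,
            "heads": [
                {"head_id": h.head_id, "motile": h.motile, "speed_um_s": h.speed_um_s}
                for h in gt.heads
            ],
        }
        scene_path.write_text(json.dumps(scene, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing scene under {out_dir}: {exc}") from exc
    return {
        "frames": out_dir / "frames",
        "annotations": ann_dir,
        "detections": det_path,
        "tracks": track_path,
        "scene": scene_path,
    }
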