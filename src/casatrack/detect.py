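"""Pluggable detection stage producing per-frame sperm-head detections.

The pipeline is detector-agnostic: any provider that emits per-frame boxes
with confidence scores can feed the tracker, including an externally trained
CNN whose output is loaded through :func:`load_external_detections`. For
self-contained runs a classical blob detector is shipped: background
subtraction, Gaussian smoothing, thresholding and connected-component
labeling, with the operator chain exposed through :class:`DetectorConfig`.

Score gating follows the strict-inequality convention (keep score > 0.8 by
default); flip ``strict_gate`` to use >= instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import filters, measure

from .core import BoundingBox, Detection
from .io import read_detection_table

__all__ = ["DetectorConfig", "filter_detections", "detect_blobs", "load_external_detections"]


@dataclass
class DetectorConfig:
    """Settings of the score gate and of the classical blob detector.

    score_threshold
        Confidence gate; detections scoring above it are kept. Default 0.8.
    strict_gate
        If True (default), keep score > threshold; if False, score >= threshold.
    min_blob_area, max_blob_area
        Connected-component area bounds in px^2 for the blob detector.
    intensity_polarity
        "bright" when heads are brighter than background, "dark" otherwise.
    max_detections_per_frame
        Hard cap on detections per frame; when exceeded, the highest-scoring
        survive. Default 100.
    smoothing_sigma
        Gaussian pre-smoothing sigma in px for the blob detector.
    """

    score_threshold: float = 0.8
    strict_gate: bool = True
    min_blob_area: float = 4.0
    max_blob_area: float = 400.0
    intensity_polarity: str = "bright"
    max_detections_per_frame: int = 100
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError(f"score_threshold must be in [0, 1], got {self.score_threshold}")
        if not self.min_blob_area < self.max_blob_area:
            raise ValueError("min_blob_area must be < max_blob_area")
        if self.max_detections_per_frame < 1:
            raise ValueError("max_detections_per_frame must be >= 1")
        if self.intensity_polarity not in ("bright", "dark"):
            raise ValueError("intensity_polarity must be 'bright' or 'dark'")


def filter_detections(
    detections: Sequence[Detection], cfg: DetectorConfig
) -> list[Detection]:
    """Apply the confidence gate and the per-frame detection cap.

    Keeps exactly the detections whose score passes the gate (strictly
    greater than the threshold by default), preserving input order; if more
    than ``max_detections_per_frame`` pass, only the highest-scoring are
    kept (still in original order).
    """
    if cfg.strict_gate:
        kept = [d for d in detections if d.score > cfg.score_threshold]
    else:
        kept = [d for d in detections if d.score >= cfg.score_threshold]
    cap = cfg.max_detections_per_frame
    if len(kept) > cap:
        # indices of the cap highest-scoring, then restore original order
        order = sorted(range(len(kept)), key=lambda i: (-kept[i].score, i))[:cap]
        kept = [kept[i] for i in sorted(order)]
    return kept


def detect_blobs(frame: np.ndarray, cfg: DetectorConfig) -> list[Detection]:
    """Detect sperm-head-like blobs in a single grayscale frame.

    Pipeline: (optional polarity inversion) -> Gaussian smoothing -> Otsu
    threshold -> connected components -> area gating. The score of each blob
    is its peak contrast above the threshold, normalized by the frame's
    maximum contrast, so it is deterministic, monotone in contrast, and
    close to 1 for any blob as bright as the brightest one in the frame.

    A uniform or degenerate frame yields an empty list, never an error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    if frame.ndim != 2 or frame.size == 0:
        return []
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if cfg.intensity_polarity == "dark":
        frame = frame.max() - frame
    if np.ptp(frame) == 0:
        return []

    smoothed = filters.gaussian(frame, sigma=cfg.smoothing_sigma, preserve_range=True)
    try:
        thresh = filters.threshold_otsu(smoothed)
    except ValueError:
        return []
    mask = smoothed > thresh
    labels = measure.label(mask, connectivity=2)
    max_contrast = smoothed.max() - thresh
    if max_contrast <= 0:
        return []

    detections = []
    for region in measure.regionprops(labels, intensity_image=smoothed):
        if not (cfg.min_blob_area <= region.area <= cfg.max_blob_area):
            continue
        r0, c0, r1, c1 = region.bbox  # half-open, matches box convention
        score = float(np.clip((region.intensity_max - thresh) / max_contrast, 0.0, 1.0))
        detections.append(
            Detection(BoundingBox(float(c0), float(r0), float(c1), float(r1)), score)
        )
    # stable top-left ordering for determinism
    detections.sort(key=lambda d: (d.box.y_min, d.box.x_min))
    if len(detections) > cfg.max_detections_per_frame:
        detections.sort(key=lambda d: -d.score)
        detections = detections[: cfg.max_detections_per_frame]
        detections.sort(key=lambda d: (d.box.y_min, d.box.x_min))
    return detections


def load_external_detections(
    path, frame_size: tuple[int, int]
) -> list[list[Detection]]:
    """Load a CNN's (or any provider's) detection table.

    Thin adapter over :func:`casatrack.io.read_detection_table`: boxes are
    converted to absolute pixels per the table's declared convention and
    grouped by frame index.
    """
    return read_detection_table(path, frame_size)
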