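"""End-to-end pipeline configuration and orchestration.

A :class:`PipelineConfig` holds every knob of the detect -> track -> assess
chain in one flat record whose defaults are the source study's constants
(score gate 0.8, association gate 80 px, 0.66 µm/px, 50 fps, 34.5 µm/s
viability cut, 58% suitability threshold). It serializes to a flat
``key = value`` text file and back losslessly; unknown keys are rejected by
name so typos in config files fail loudly.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import Detection, Track
from .detect import DetectorConfig, detect_blobs, filter_detections
from .motility import Calibration, VitalityReport, compute_vitality
from .tracker import TrackerConfig, run as run_tracker

__all__ = ["PipelineConfig", "run_pipeline", "analyze_frames"]

logger = logging.getLogger("casatrack")


@dataclass
class PipelineConfig:
    """Flat configuration of the whole analysis chain."""

    # detector
    score_threshold: float = 0.8
    strict_gate: bool = True
    min_blob_area: float = 4.0
    max_blob_area: float = 400.0
    intensity_polarity: str = "bright"
    max_detections_per_frame: int = 100
    smoothing_sigma: float = 1.0
    # tracker
    gate_px: float = 80.0
    max_missed_frames: int = 5
    matching: str = "greedy"
    reset_fraction: float | None = None
    # calibration
    um_per_px: float = 0.66
    fps: float = 50.0
    viable_speed_um_s: float = 34.5
    magnification: float = 400.0
    # vitality
    vitality_mode: str = "count"
    suitability_threshold_pct: float = 58.0
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            score_threshold=self.score_threshold,
            strict_gate=self.strict_gate,
            min_blob_area=self.min_blob_area,
            max_blob_area=self.max_blob_area,
            intensity_polarity=self.intensity_polarity,
            max_detections_per_frame=self.max_detections_per_frame,
            smoothing_sigma=self.smoothing_sigma,
        )

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(
            gate_px=self.gate_px,
            max_missed_frames=self.max_missed_frames,
            matching=self.matching,
            reset_fraction=self.reset_fraction,
        )

    def calibration(self) -> Calibration:
        return Calibration(
            um_per_px=self.um_per_px,
            fps=self.fps,
            viable_speed_um_s=self.viable_speed_um_s,
            magnification=self.magnification,
        )

    # -- flat key=value serialization ------------------------------------

    def to_file(self, path: str | os.PathLike) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'none' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value', got {line!r}")
            key, _, raw = (s.strip() for s in line.partition("="))
            if key not in fields:
                raise ValueError(f"{path}: line {lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(raw, fields[key].type)
        return cls(**kwargs)


def _parse_value(raw: str, annotation: str):
    if raw.lower() == "none":
        return None
    if "bool" in str(annotation):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse {raw!r} as bool")
    if str(annotation).startswith("int"):
        return int(raw)
    if "float" in str(annotation):
        return float(raw)
    return raw


# ---------------------------------------------------------------------------


def run_pipeline(
    frames_detections: Sequence[Sequence[Detection]],
    config: PipelineConfig | None = None,
) -> tuple[VitalityReport, list[Track]]:
    """Score-filter per-frame detections, track, and assess vitality.

    The main entry point when detections come from an external provider
    (a CNN, the simulator, or a detection table). Returns the sample-level
    report and every track produced.
    """
    config = config or PipelineConfig()
    det_cfg = config.detector_config()
    filtered = [filter_detections(dets, det_cfg) for dets in frames_detections]
    n_in = sum(len(d) for d in frames_detections)
    n_kept = sum(len(d) for d in filtered)
    logger.info("detections: %d read, %d passed score gate", n_in, n_kept)

    tracks = run_tracker(filtered, config.tracker_config())
    logger.info("tracking: %d tracks over %d frames", len(tracks), len(frames_detections))

    report = compute_vitality(
        tracks,
        config.calibration(),
        mode=config.vitality_mode,
        suitability_threshold_pct=config.suitability_threshold_pct,
    )
    logger.info(
        "vitality: found=%d live=%d viable=%d -> %.1f%% (%s)",
        report.n_found,
        report.n_live,
        report.n_viable,
        report.vitality_pct,
        "suitable" if report.suitable else "not suitable",
    )
    return report, tracks


def analyze_frames(
    frames, config: PipelineConfig | None = None
) -> tuple[VitalityReport, list[Track]]:
    """Run the classical blob detector over raw frames, then the pipeline."""
    config = config or PipelineConfig()
    det_cfg = config.detector_config()
    frames_detections = [detect_blobs(frame, det_cfg) for frame in frames]
    return run_pipeline(frames_detections, config)
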