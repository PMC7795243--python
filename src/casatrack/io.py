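"""Readers and writers for the formats around the pipeline.

* Pascal VOC XML annotations, one file per frame, in the dialect emitted by
  the LabelImg tool (``folder``/``filename``/``size``/``object``/``bndbox``
  elements, integer box coordinates).
* Delimited detection tables (``frame,xmin,ymin,xmax,ymax,score``) with a
  leading header line declaring whether coordinates are normalized to [0, 1]
  or absolute pixels.
* Delimited track tables (per-point and per-track summary).
* PNG frame directories, ordered by zero-padded index.

All boxes are absolute pixels in memory; normalized detector output is
converted here, at the I/O boundary, using the frame size.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from lxml import etree

from .core import BoundingBox, Detection, Track

__all__ = [
    "write_voc_xml",
    "read_voc_xml",
    "write_detection_table",
    "read_detection_table",
    "write_track_table",
    "write_track_summary",
    "write_frames",
    "read_frames",
]

_COORDS_RE = re.compile(r"#\s*coords\s*=\s*(normalized|absolute)\s*$")


# ---------------------------------------------------------------------------
# Pascal VOC XML (LabelImg dialect)

def write_voc_xml(
    path: str | os.PathLike,
    filename: str,
    frame_size: tuple[int, int],
    boxes: Sequence[BoundingBox],
    label: str = "sperm_head",
) -> None:
    """Write one LabelImg-compatible VOC annotation file.

    ``frame_size`` is (width, height); box coordinates are rounded to
    integers per the VOC dialect.
    """
    width, height = frame_size
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = str(Path(path).parent.name)
    etree.SubElement(root, "filename").text = filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(width))
    etree.SubElement(size, "height").text = str(int(height))
    etree.SubElement(size, "depth").text = "1"
    etree.SubElement(root, "segmented").text = "0"
    for box in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(box.x_min)))
        etree.SubElement(bnd, "ymin").text = str(int(round(box.y_min)))
        etree.SubElement(bnd, "xmax").text = str(max(int(round(box.x_max)),
                                                     int(round(box.x_min)) + 1))
        etree.SubElement(bnd, "ymax").text = str(max(int(round(box.y_max)),
                                                     int(round(box.y_min)) + 1))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, encoding="utf-8")


def read_voc_xml(path: str | os.PathLike) -> tuple[tuple[int, int], list[BoundingBox]]:
    """Read a VOC annotation file; returns ((width, height), boxes)."""
    tree = etree.parse(str(path))
    size = tree.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes = []
    for obj in tree.iterfind("object"):
        bnd = obj.find("bndbox")
        boxes.append(
            BoundingBox(
                float(bnd.findtext("xmin")),
                float(bnd.findtext("ymin")),
                float(bnd.findtext("xmax")),
                float(bnd.findtext("ymax")),
            )
        )
    return (width, height), boxes


# ---------------------------------------------------------------------------
# Detection tables

def write_detection_table(
    path: str | os.PathLike,
    frames_detections: Iterable[Sequence[Detection]],
    coords: str = "absolute",
    frame_size: tuple[int, int] | None = None,
) -> None:
    """Write per-frame detections as delimited text.

    First line declares the coordinate convention (``# coords=absolute`` or
    ``# coords=normalized``); normalized output requires ``frame_size``.
    """
    if coords not in ("absolute", "normalized"):
        raise ValueError(f"coords must be 'absolute' or 'normalized', got {coords!r}")
    if coords == "normalized" and frame_size is None:
        raise ValueError("frame_size is required to write normalized coordinates")
    rows = []
    for frame_index, dets in enumerate(frames_detections):
        for d in dets:
            b = d.box
            x0, y0, x1, y1 = b.x_min, b.y_min, b.x_max, b.y_max
            if coords == "normalized":
                w, h = frame_size
                x0, y0, x1, y1 = x0 / w, y0 / h, x1 / w, y1 / h
            rows.append((frame_index, x0, y0, x1, y1, d.score))
    df = pd.DataFrame(rows, columns=["frame", "xmin", "ymin", "xmax", "ymax", "score"])
    with open(path, "w") as fh:
        fh.write(f"# coords={coords}\n")
        df.to_csv(fh, index=False)


def read_detection_table(
    path: str | os.PathLike, frame_size: tuple[int, int]
) -> list[list[Detection]]:
    """Load a detection table into per-frame Detection lists.

    Boxes are converted to absolute pixels using ``frame_size`` when the
    header declares normalized coordinates; output is grouped and ordered by
    frame index (empty frames between occupied ones yield empty lists).
    Malformed rows raise with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        m = _COORDS_RE.match(header.strip())
        if not m:
            raise ValueError(
                f"{path}: first line must declare '# coords=normalized|absolute', "
                f"got {header.strip()!r}"
            )
        coords = m.group(1)
        lines = fh.readlines()
    if not lines:
        return []
    columns = [c.strip() for c in lines[0].strip().split(",")]
    expected = ["frame", "xmin", "ymin", "xmax", "ymax", "score"]
    if columns != expected:
        raise ValueError(f"{path}: line 2: expected columns {expected}, got {columns}")

    w, h = frame_size
    records: list[tuple[int, Detection]] = []
    for lineno, line in enumerate(lines[1:], start=3):
        if not line.strip():
            continue
        parts = line.strip().split(",")
        try:
            frame = int(parts[0])
            x0, y0, x1, y1, score = (float(v) for v in parts[1:6])
            if len(parts) != 6:
                raise ValueError("wrong field count")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row {line.strip()!r}") from exc
        if coords == "normalized":
            if not all(0.0 <= v <= 1.0 for v in (x0, y0, x1, y1)):
                raise ValueError(
                    f"{path}: line {lineno}: coordinates declared normalized but "
                    f"outside [0, 1]: {(x0, y0, x1, y1)}"
                )
            x0, x1 = x0 * w, x1 * w
            y0, y1 = y0 * h, y1 * h
        records.append((frame, Detection(BoundingBox(x0, y0, x1, y1), score)))

    if not records:
        return []
    n_frames = max(f for f, _ in records) + 1
    out: list[list[Detection]] = [[] for _ in range(n_frames)]
    for frame, det in records:
        out[frame].append(det)
    return out


# ---------------------------------------------------------------------------
# Track tables

def write_track_table(path: str | os.PathLike, tracks: Sequence[Track]) -> None:
    """Per-point track table: columns track_id, frame, x, y."""
    rows = [
        (t.track_id, frame, p.x, p.y)
        for t in sorted(tracks, key=lambda t: t.track_id)
        for frame, p in t.centroids
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"]).to_csv(path, index=False)


def write_track_summary(
    path: str | os.PathLike, tracks: Sequence[Track], fps: float
) -> None:
    """Per-track summary: track_id, n_points, total_distance_px, duration_s."""
    rows = []
    for t in sorted(tracks, key=lambda t: t.track_id):
        duration = (t.last_frame - t.first_frame) / fps if t.n_points >= 2 else 0.0
        rows.append((t.track_id, t.n_points, t.total_distance_px, duration))
    pd.DataFrame(
        rows, columns=["track_id", "n_points", "total_distance_px", "duration_s"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Frames

def write_frames(out_dir: str | os.PathLike, frames: Sequence[np.ndarray]) -> list[Path]:
    """Write frames as zero-padded PNG files; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:05d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_frames(in_dir: str | os.PathLike) -> list[np.ndarray]:
    """Read all PNG frames from a directory in index order."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no .png frames found in {in_dir}")
    return [iio.imread(p) for p in paths]
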