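"""Evaluation statistics for detection quality and vitality prediction.

Detection quality is measured by greedy IoU matching of predicted to
ground-truth boxes (IoU >= 0.5 by convention), yielding true/false
positives and false negatives; "accuracy" is reported as tp/(tp+fp+fn)
since detection has no true negatives, with precision and recall always
alongside. Vitality prediction quality is measured against experimental
values by per-sample absolute deviation, mean absolute error (the two are
definitionally identical on the same pairs), Pearson correlation with a
seeded percentile-bootstrap confidence interval, and the ZeroR baseline
(predict the dataset mean; an informative predictor must beat its MAE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import BoundingBox, Detection

__all__ = [
    "iou",
    "match_detections",
    "detection_metrics",
    "deviation_table",
    "vitality_stats",
    "bootstrap_ci",
    "speed_comparison",
    "EvalResult",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    pred: Sequence[Detection],
    gt_boxes: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy IoU matching of predictions to ground truth: (tp, fp, fn).

    Predictions are visited in descending score order; each claims the
    unmatched ground-truth box of highest IoU, provided it reaches the
    threshold. Counts are conserved: tp + fp = |pred|, tp + fn = |gt|.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].score, i))
    unmatched_gt = set(range(len(gt_boxes)))
    tp = 0
    for i in order:
        best_j, best_v = None, 0.0
        for j in sorted(unmatched_gt):  # sorted: deterministic tie-break
            v = iou(pred[i].box, gt_boxes[j])
            if v >= iou_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j is not None:
            unmatched_gt.discard(best_j)
            tp += 1
    fp = len(pred) - tp
    fn = len(gt_boxes) - tp
    return tp, fp, fn


def detection_metrics(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Precision, recall and TN-free accuracy tp/(tp+fp+fn) from counts."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return {"precision": precision, "recall": recall, "accuracy": accuracy}


def deviation_table(
    pairs: Sequence[tuple[float, float]],
) -> tuple[list[float], float]:
    """Per-sample viability deviations |experimental - estimated| and their mean.

    Inputs are percentages in [0, 100]; deviations stay integer when the
    inputs are integer, and the mean is an arithmetic mean (report to one
    decimal place).
    """
    if not pairs:
        raise ValueError("deviation_table requires at least one pair")
    for e, p in pairs:
        if not (0.0 <= e <= 100.0 and 0.0 <= p <= 100.0):
            raise ValueError(f"percentages must be in [0, 100], got {(e, p)}")
    deviations = [abs(e - p) for e, p in pairs]
    return deviations, float(np.mean(deviations))


def vitality_stats(pairs: Sequence[tuple[float, float]]) -> dict[str, float]:
    """MAE, Pearson r and the ZeroR-baseline MAE of vitality prediction.

    ZeroR predicts the mean of the actual values for every sample; its MAE
    is the mean absolute deviation of the actuals. Pearson r requires >= 3
    pairs and non-degenerate margins (raises otherwise).
    """
    if len(pairs) < 3:
        raise ValueError("vitality_stats requires at least 3 pairs for Pearson r")
    actual = np.array([a for a, _ in pairs], dtype=float)
    predicted = np.array([p for _, p in pairs], dtype=float)
    if np.std(actual) == 0 or np.std(predicted) == 0:
        raise ValueError("Pearson r undefined: zero variance in one margin")
    mae = float(np.mean(np.abs(actual - predicted)))
    r = float(stats.pearsonr(actual, predicted).statistic)
    zero_r_mae = float(np.mean(np.abs(actual - actual.mean())))
    return {"mae": mae, "pearson_r": r, "zero_r_mae": zero_r_mae}


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of a statistic of one sample.

    Resamples with replacement ``n_boot`` times and returns the empirical
    (alpha/2, 1 - alpha/2) percentiles. Deterministic per seed; a constant
    sample yields a degenerate interval.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap_ci requires at least 2 values")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    if statistic is np.mean:  # vectorized fast path
        boot = values[idx].mean(axis=1)
    else:
        boot = np.array([statistic(values[row]) for row in idx])
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def speed_comparison(
    motile_speeds: Sequence[float],
    nonmotile_speeds: Sequence[float],
    paired: bool = False,
) -> dict[str, float]:
    """Compare motile vs non-motile track speeds.

    The groups are distinct tracks, hence unpaired; Welch's t-test is the
    default. A paired variant (requiring equal lengths) is available for
    comparability with analyses that applied a paired test to these groups,
    but note that pairing unrelated tracks has no statistical justification.
    """
    a = np.asarray(motile_speeds, dtype=float)
    b = np.asarray(nonmotile_speeds, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "motile_mean": float(a.mean()),
        "nonmotile_mean": float(b.mean()),
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
    }


@dataclass
class EvalResult:
    """Bundled evaluation report (detection block + vitality block)."""

    detection: dict[str, float] = field(default_factory=dict)
    vitality: dict[str, float] = field(default_factory=dict)
    deviations: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "detection": self.detection,
            "vitality": self.vitality,
            "deviations": self.deviations,
        }
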