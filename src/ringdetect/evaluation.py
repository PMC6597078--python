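"""Detection evaluation: IoU matching, precision/recall/F1, MR-FPPI, LAMR.

Boxes are (x_min, y_min, x_max, y_max) with 0-based *inclusive* integer
corners, so a box's width is x_max - x_min + 1 pixels; the overlap measure
alpha0 is intersection area over union area under that convention.  A
positive detection is correct when alpha0 with an unclaimed ground-truth
box exceeds 0.5; matching is greedy in descending score and one-to-one.

The miss-rate vs false-positives-per-image (MR-FPPI) curve sweeps the
distinct detection scores as thresholds; the log-average miss rate (LAMR)
summarises it by averaging MR at nine FPPI values evenly log-spaced over
[1e-2, 1] (geometric mean by default, arithmetic available), reading the
curve as a step function and taking MR = 1 left of the first point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsift import InvalidInputError

__all__ = [
    "MatchCounts",
    "overlap_alpha0",
    "match_detections",
    "precision_recall_f1",
    "mr_fppi_curve",
    "log_average_miss_rate",
    "LAMR_FLOOR",
]

#: miss rates are floored here before geometric averaging
LAMR_FLOOR = 1e-10


@dataclass
class MatchCounts:
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.n_tp + other.n_tp, self.n_fp + other.n_fp, self.n_fn + other.n_fn
        )


def _check_box(b) -> tuple:
    x0, y0, x1, y1 = (float(v) for v in b)
    if x0 > x1 or y0 > y1:
        raise InvalidInputError(f"degenerate box {tuple(b)} (min corner > max corner)")
    return x0, y0, x1, y1


def overlap_alpha0(box_a, box_b) -> float:
    """Inclusive-pixel intersection-over-union of two boxes; in [0, 1]."""
    ax0, ay0, ax1, ay1 = _check_box(box_a)
    bx0, by0, bx1, by1 = _check_box(box_b)
    ix = min(ax1, bx1) - max(ax0, bx0) + 1
    iy = min(ay1, by1) - max(ay0, by0) + 1
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (ax1 - ax0 + 1) * (ay1 - ay0 + 1)
    area_b = (bx1 - bx0 + 1) * (by1 - by0 + 1)
    return inter / (area_a + area_b - inter)


def match_detections(detections, ground_truth, overlap_threshold: float = 0.5) -> MatchCounts:
    """Greedy one-to-one matching of scored detections to ground-truth boxes.

    ``detections`` is a sequence of (box, score) pairs (or objects with
    ``.box``/``.score``); ``ground_truth`` a sequence of boxes.  Detections
    are visited in descending score; each claims the unmatched ground-truth
    box of highest alpha0 provided alpha0 > ``overlap_threshold``.
    Unmatched detections count as false positives, unclaimed ground-truth
    boxes as false negatives.
    """
    dets = [
        (d.box, d.score) if hasattr(d, "box") else (d[0], d[1]) for d in detections
    ]
    dets.sort(key=lambda t: -t[1])
    gt = [_check_box(b) for b in ground_truth]
    claimed = [False] * len(gt)
    n_tp = 0
    for box, _score in dets:
        best_j, best_ov = -1, overlap_threshold
        for j, g in enumerate(gt):
            if claimed[j]:
                continue
            ov = overlap_alpha0(box, g)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            claimed[best_j] = True
            n_tp += 1
    return MatchCounts(
        n_tp=n_tp, n_fp=len(dets) - n_tp, n_fn=len(gt) - n_tp
    )


def precision_recall_f1(counts: MatchCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 cases are 0."""
    tp, fp, fn = counts.n_tp, counts.n_fp, counts.n_fn
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def mr_fppi_curve(detections_per_image, ground_truth_per_image, n_images: int | None = None):
    """MR vs FPPI swept over the distinct detection scores.

    Parameters
    ----------
    detections_per_image : list (one entry per image) of lists of
        (box, score) pairs or Detection-like objects.
    ground_truth_per_image : list of lists of ground-truth boxes.

    Returns
    -------
    list of (threshold, fppi, mr) tuples ordered by decreasing threshold
    (hence nondecreasing FPPI); a detector with no detections yields the
    single point (inf, 0.0, 1.0).
    """
    if n_images is None:
        n_images = len(detections_per_image)
    if n_images < 1:
        raise InvalidInputError("need at least one image")
    if len(detections_per_image) != len(ground_truth_per_image):
        raise InvalidInputError("detections and ground truth must align per image")
    n_gt = sum(len(g) for g in ground_truth_per_image)
    if n_gt == 0:
        raise InvalidInputError("no ground-truth boxes given")

    all_scores = sorted(
        {
            (d.score if hasattr(d, "score") else d[1])
            for dets in detections_per_image
            for d in dets
        },
        reverse=True,
    )
    if not all_scores:
        return [(np.inf, 0.0, 1.0)]

    curve = []
    for thr in all_scores:
        total = MatchCounts()
        for dets, gt in zip(detections_per_image, ground_truth_per_image):
            kept = [
                d for d in dets
                if (d.score if hasattr(d, "score") else d[1]) >= thr
            ]
            total = total + match_detections(kept, gt)
        fppi = total.n_fp / n_images
        mr = total.n_fn / (total.n_fn + total.n_tp)
        curve.append((float(thr), float(fppi), float(mr)))
    return curve


def log_average_miss_rate(curve, mode: str = "geometric") -> float:
    """Average MR at nine FPPI values 10^-2 ... 10^0 (log-spaced, step 10^0.25).

    For each reference FPPI the curve is read as a step function: the MR of
    the largest achieved FPPI <= reference, or 1 when the curve never gets
    that low.  ``mode`` selects the geometric (default; MR floored at
    ``LAMR_FLOOR``) or arithmetic mean.
    """
    if len(curve) == 0:
        raise InvalidInputError("empty MR-FPPI curve")
    if mode not in ("geometric", "arithmetic"):
        raise InvalidInputError(f"unknown averaging mode {mode!r}")
    best: dict[float, float] = {}
    for _thr, fppi, mr in _as_points(curve):
        best[fppi] = min(mr, best.get(fppi, 1.0))
    pts = sorted(best.items())
    refs = 10.0 ** (-2.0 + 0.25 * np.arange(9))
    samples = []
    for ref in refs:
        mr = 1.0
        for fppi, m in pts:
            if fppi <= ref * (1 + 1e-12):
                mr = m
            else:
                break
        samples.append(mr)
    samples = np.asarray(samples)
    if mode == "arithmetic":
        return float(samples.mean())
    return float(np.exp(np.log(np.maximum(samples, LAMR_FLOOR)).mean()))


def _as_points(curve):
    """Accept both (thr, fppi, mr) and (fppi, mr) point formats."""
    out = []
    for p in curve:
        if len(p) == 3:
            out.append(p)
        else:
            out.append((np.nan, p[0], p[1]))
    return out
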