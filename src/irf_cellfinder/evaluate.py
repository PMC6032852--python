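"""Bounding-box Dice evaluation: pairwise Dice, the Dice matrix, the two
asymmetric average Dice scores, and recall/precision at a Dice threshold.

Evaluation is done on rectangular bounding boxes, the unit that defines
a field of view for follow-up high-resolution imaging. For detections
``i`` and ground-truth objects ``j``:

    D_ij = 2 |A_i & B_j| / (|A_i| + |B_j|)

The average over row maxima (Dbar_det) scores the detections that were
found; the average over column maxima (Dbar_GT) scores how well the
ground truth is covered. The two are neither equivalent nor symmetric.
A detection is correct when its one-to-one matched Dice exceeds the
threshold (default 0.5, strictly greater).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_io import BBox, DetectionSet, GroundTruthSet


@dataclass(frozen=True)
class DiceMatrix:
    """N_det x N_GT matrix of pairwise bounding-box Dice indices."""

    values: np.ndarray
    det_ids: tuple[int, ...]
    gt_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("Dice matrix must be 2D")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("Dice values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class EvalResult:
    """Detection scores for one image at a fixed Dice threshold.

    ``undefined_recall``/``undefined_precision`` flag empty ground-truth
    or detection sets, where the corresponding rate is reported as 0.
    """

    mean_dice_det: float
    mean_dice_gt: float
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    threshold: float
    undefined_recall: bool = False
    undefined_precision: bool = False


def dice(a: BBox, b: BBox) -> float:
    """Dice index of two boxes: 2*intersection / (area_a + area_b)."""
    return 2.0 * a.intersection_area(b) / (a.area + b.area)


def dice_matrix(dets: DetectionSet, gt: GroundTruthSet) -> DiceMatrix:
    """All-pairs Dice between a detection set and a ground-truth set."""
    values = np.array(
        [[dice(d, g) for g in gt.boxes] for d in dets.boxes], dtype=float
    ).reshape(len(dets), len(gt))
    return DiceMatrix(values=values, det_ids=tuple(range(len(dets))), gt_ids=tuple(range(len(gt))))


def mean_dice(dm: DiceMatrix, axis: Literal["det", "gt"]) -> float:
    """Average best-match Dice over detections (``det``) or ground truth (``gt``).

    ``det``: mean over rows of the row maximum — how good the found
    detections are. ``gt``: mean over columns of the column maximum —
    how well the ground truth is covered. The averaged axis must be
    nonempty; maxima over an empty opposing axis count as 0.
    """
    n_det, n_gt = dm.shape
    if axis == "det":
        if n_det == 0:
            raise ValueError("mean dice over detections is undefined: no detections")
        return float(np.mean(dm.values.max(axis=1))) if n_gt else 0.0
    if axis == "gt":
        if n_gt == 0:
            raise ValueError("mean dice over ground truth is undefined: no ground-truth objects")
        return float(np.mean(dm.values.max(axis=0))) if n_det else 0.0
    raise ValueError(f"axis must be 'det' or 'gt', got {axis!r}")


def _greedy_match(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """One-to-one matching by descending Dice; pairs with D > threshold only."""
    n_det, n_gt = values.shape
    order = np.argsort(values, axis=None)[::-1]
    matched_det: set[int] = set()
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), n_gt) if n_gt else (0, 0)
        d = values[i, j]
        if d <= threshold:
            break
        if i in matched_det or j in matched_gt:
            continue
        matched_det.add(i)
        matched_gt.add(j)
        pairs.append((i, j))
    return pairs


def match_and_score(
    dets: DetectionSet, gt: GroundTruthSet, threshold: float = 0.5
) -> EvalResult:
    """Match detections to ground truth one-to-one and score the result.

    Pairs are accepted greedily by descending Dice, each detection and
    ground-truth object at most once, and only while D > ``threshold``
    (strictly). Accepted pairs are true positives; unmatched ground
    truth are false negatives; unmatched detections are false
    positives. Empty sets give 0 rates with a warning flag rather than
    an exception, so batch evaluation never aborts.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    dm = dice_matrix(dets, gt)
    n_det, n_gt = dm.shape
    tp = len(_greedy_match(dm.values, threshold)) if n_det and n_gt else 0
    fn = n_gt - tp
    fp = n_det - tp

    undefined_recall = n_gt == 0
    undefined_precision = n_det == 0
    if undefined_recall or undefined_precision:
        warnings.warn(
            "empty detection or ground-truth set: undefined recall/precision reported as 0",
            stacklevel=2,
        )
    recall = tp / n_gt if n_gt else 0.0
    precision = tp / n_det if n_det else 0.0
    return EvalResult(
        mean_dice_det=mean_dice(dm, "det") if n_det else 0.0,
        mean_dice_gt=mean_dice(dm, "gt") if n_gt else 0.0,
        tp=tp,
        fp=fp,
        fn=fn,
        recall=recall,
        precision=precision,
        threshold=threshold,
        undefined_recall=undefined_recall,
        undefined_precision=undefined_precision,
    )


def agreement_matrix(sets: Sequence[GroundTruthSet]) -> pd.DataFrame:
    """All-vs-all annotator agreement table.

    Entry (row k, col l) treats annotator k's boxes as detections and
    annotator l's as ground truth and reports the ground-truth-side
    average Dice (Dbar_GT, column maxima of the Dice matrix). The
    diagonal is 1 by construction; the matrix is generally asymmetric
    because the two averaging directions differ.
    """
    if len(sets) < 2:
        raise ValueError("need at least two annotator sets")
    shapes = {s.image_shape for s in sets if s.image_shape is not None}
    if len(shapes) > 1:
        raise ValueError(f"annotator sets come from different images: {shapes}")
    names = [s.annotator_id or f"annotator_{k}" for k, s in enumerate(sets)]
    n = len(sets)
    out = np.ones((n, n))
    for k in range(n):
        for l in range(n):
            if k == l:
                continue
            as_dets = DetectionSet(boxes=sets[k].boxes, image_id=names[k])
            dm = dice_matrix(as_dets, sets[l])
            out[k, l] = mean_dice(dm, "gt") if len(sets[l]) else 0.0
    return pd.DataFrame(out, index=names, columns=names)
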