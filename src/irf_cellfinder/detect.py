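"""Marker-controlled watershed detection of fluorescent cells.

The detector works on the preprocessed image: a scale-normalized
Laplacian-of-Gaussian (LoG) feature highlights the ring/disk profiles
of sectioned cells; the brightest fraction of the feature supplies cell
markers; the ridge skeleton of the distance transform of the marker
complement supplies background markers; a watershed of the feature's
gradient magnitude, seeded at both marker sets, partitions the image;
and the resulting labels are reduced to bounding boxes which are merged
and size-filtered.

Detection is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import medial_axis
from skimage.segmentation import watershed

from .core_io import BBox, DetectionSet, Image2D
from .preprocess import PreprocessConfig, preprocess


@dataclass(frozen=True)
class DetectConfig:
    """Tunable parameters of the watershed detector.

    Attributes
    ----------
    log_sigma : float
        Scale (px) of the Laplacian-of-Gaussian feature; 7 px matches
        the ring-border width of sectioned cells at 178 nm/px.
    marker_quantile : float
        Empirical-CDF threshold for cell markers; 0.92 keeps the 8%
        brightest feature pixels.
    min_area_px, max_area_px : int
        Bounding-box area bounds of the size filter. The defaults
        (500, 20000 px) correspond to cell cross-sections roughly
        4-25 um across at 178 nm/px; anything smaller is treated as a
        noise basin rather than a cell.
    merge_overlap : float
        Intersection-over-minimum-area at or above which two boxes are
        considered fragments of the same cell and merged.
    """

    log_sigma: float = 7.0
    marker_quantile: float = 0.92
    min_area_px: int = 500
    max_area_px: int = 20000
    merge_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.marker_quantile < 1):
            raise ValueError("marker_quantile must be in (0, 1)")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("require 0 < min_area_px < max_area_px")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if not (0 <= self.merge_overlap <= 1):
            raise ValueError("merge_overlap must be in [0, 1]")


@dataclass(frozen=True)
class LabelMap:
    """Integer-labeled segmentation raster; 0 is background/watershed line."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.min() < 0:
            raise ValueError("labels must be a 2D nonnegative integer array")
        object.__setattr__(self, "labels", lab)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def log_feature(img: Image2D, sigma: float) -> Image2D:
    """Scale-normalized, negated Laplacian of Gaussian.

    Bright blobs and rings of spatial scale ~``sigma`` give a high
    positive response; the negation makes the sign convention
    bright-is-positive. Scale normalization (multiplication by sigma^2)
    makes responses comparable across scales.
    """
    pixels = np.asarray(img.pixels, dtype=float)
    return img.with_pixels(-(sigma**2) * ndi.gaussian_laplace(pixels, sigma))


def cell_markers(feature: Image2D, quantile: float) -> np.ndarray:
    """Candidate cell pixels: feature values at or above the given quantile.

    Returns a boolean mask that is True exactly where
    ``feature >= quantile(feature)``; with all-distinct values the True
    fraction is 1 - quantile (ties at the threshold are included).
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    pixels = np.asarray(feature.pixels, dtype=float)
    if pixels.max() == pixels.min():
        raise ValueError("constant feature image: no meaningful quantile (upstream failure?)")
    return pixels >= np.quantile(pixels, quantile)


def gradient_magnitude(feature: Image2D) -> Image2D:
    """Elementwise magnitude of the Sobel first-derivative filters.

    Normalized so a unit-slope ramp yields magnitude 1 in the image
    interior; isotropic under 90-degree rotation.
    """
    pixels = np.asarray(feature.pixels, dtype=float)
    gr = ndi.sobel(pixels, axis=0) / 8.0
    gc = ndi.sobel(pixels, axis=1) / 8.0
    return feature.with_pixels(np.hypot(gr, gc))


def background_markers(cell_mask: np.ndarray) -> np.ndarray:
    """Thin set of pixels maximally distant from the candidate cells.

    Computes the ridge skeleton (medial axis) of the distance transform
    of the complement of ``cell_mask``: the locus of background pixels
    equidistant from two or more candidate-cell structures, which seeds
    the background basin of the watershed. Always disjoint from
    ``cell_mask``.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any() or cell_mask.all():
        raise ValueError("degenerate cell mask (all background or all cells)")
    skel = medial_axis(~cell_mask)
    return skel & ~cell_mask


def segment(feature_grad: Image2D, cell_mask: np.ndarray, bg_mask: np.ndarray) -> LabelMap:
    """Marker-controlled watershed of the gradient image.

    Minima are imposed at both marker sets (each connected cell-marker
    component is one seed; the background skeleton is a single seed).
    Basins flooded from the background seed are relabeled 0; the
    remaining basins get labels 1..K, each containing at least one
    cell-marker pixel.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    grad = np.asarray(feature_grad.pixels, dtype=float)
    if cell_mask.shape != grad.shape or bg_mask.shape != grad.shape:
        raise ValueError("masks must match the gradient image shape")
    if (cell_mask & bg_mask).any():
        raise ValueError("cell and background markers must be disjoint")
    if not cell_mask.any():
        return LabelMap(np.zeros(grad.shape, dtype=np.int32))
    seeds, n_cells = ndi.label(cell_mask)
    markers = np.where(cell_mask, seeds + 1, 0).astype(np.int32)
    markers[bg_mask] = 1  # single background seed
    basins = watershed(grad, markers=markers)
    labels = np.where(basins > 1, basins - 1, 0).astype(np.int32)
    return LabelMap(labels)


def labels_to_boxes(lm: LabelMap, image_id: str = "") -> DetectionSet:
    """One tight bounding box per positive label, label id preserved."""
    boxes = tuple(
        BBox(*p.bbox, label=int(p.label))
        for p in regionprops(np.asarray(lm.labels))
    )
    return DetectionSet(boxes=boxes, image_id=image_id, image_shape=lm.labels.shape)


def _merge_to_fixed_point(boxes: list[BBox], merge_overlap: float) -> list[BBox]:
    """Replace any pair with intersection-over-min-area >= threshold by
    its union box, repeated until no pair qualifies."""
    changed = True
    while changed:
        changed = False
        out: list[BBox] = []
        consumed = [False] * len(boxes)
        for i, bi in enumerate(boxes):
            if consumed[i]:
                continue
            for j in range(i + 1, len(boxes)):
                if consumed[j]:
                    continue
                bj = boxes[j]
                inter = bi.intersection_area(bj)
                min_area = min(bi.area, bj.area)
                if inter / min_area >= merge_overlap:
                    bi = replace(bi.union_box(bj), label=bi.label)
                    consumed[j] = True
                    changed = True
            out.append(bi)
        boxes = out
    return boxes


def postprocess_boxes(dets: DetectionSet, cfg: DetectConfig) -> DetectionSet:
    """Drop oversized boxes, merge fragmented detections, drop undersized ones.

    An oversized box is never a cell (it is a background basin) and must
    go before merging, or it would absorb every detection it overlaps.
    Watershed oversegmentation leaves several heavily overlapping boxes
    on one cell; those are merged (union box, iterated to a fixed
    point) before the lower size bound is applied, so small fragments
    can still assemble into a full-size cell. Result is ordered by
    descending area.
    """
    boxes = [b for b in dets.boxes if b.area <= cfg.max_area_px]
    boxes = _merge_to_fixed_point(boxes, cfg.merge_overlap)
    boxes = [b for b in boxes if cfg.min_area_px <= b.area <= cfg.max_area_px]
    boxes.sort(key=lambda b: b.area, reverse=True)
    return DetectionSet(boxes=tuple(boxes), image_id=dets.image_id, image_shape=dets.image_shape)


def detect_cells(img: Image2D, pcfg: PreprocessConfig, dcfg: DetectConfig) -> DetectionSet:
    """Full detection pipeline on a raw section image.

    preprocess -> LoG feature -> {cell markers, gradient, background
    markers} -> marker-controlled watershed -> boxes -> merge + size
    filter. A blank (constant) image yields zero detections.
    """
    image_id = getattr(img, "image_id", "")
    pre = preprocess(img, pcfg)
    feat = log_feature(pre, dcfg.log_sigma)
    fpix = np.asarray(feat.pixels)
    if fpix.max() == fpix.min():
        return DetectionSet(boxes=(), image_id=image_id, image_shape=img.shape)
    cells = cell_markers(feat, dcfg.marker_quantile)
    if not cells.any() or cells.all():
        return DetectionSet(boxes=(), image_id=image_id, image_shape=img.shape)
    bg = background_markers(cells)
    grad = gradient_magnitude(feat)
    lm = segment(grad, cells, bg)
    dets = labels_to_boxes(lm, image_id=image_id)
    return postprocess_boxes(dets, dcfg)
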