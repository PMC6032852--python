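"""Typed raster/ROI containers and readers/writers for the formats the pipeline touches.

Coordinate convention: all boxes are 0-based, half-open, (row, col) order,
so a box spans the pixel block ``[row0, row1) x [col0, col1)``. ImageJ's
``(x, y, width, height)`` convention is converted on import.
"""

from __future__ import annotations

import io
import json
import logging
import struct
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Default physical pixel edge of the widefield fluorescence images, in nm.
DEFAULT_PIXEL_SIZE_NM = 178.0


@dataclass(frozen=True)
class Image2D:
    """Single-channel raster with physical pixel-size metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensity values in arbitrary units.
    pixel_size_nm : float
        Physical edge length of one pixel in nanometres.
    bit_depth : int
        Native bit depth hint of the source data (8 or 16 for camera
        data; 32 for float intermediates).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"Image2D requires a 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D intensities must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Return a copy carrying new pixel data but the same metadata."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True, order=True)
class BBox:
    """Axis-aligned rectangular detection in half-open pixel coordinates."""

    row0: int
    col0: int
    row1: int
    col1: int
    label: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def intersection_area(self, other: "BBox") -> int:
        h = min(self.row1, other.row1) - max(self.row0, other.row0)
        w = min(self.col1, other.col1) - max(self.col0, other.col0)
        return max(0, h) * max(0, w)

    def union_box(self, other: "BBox") -> "BBox":
        return BBox(
            min(self.row0, other.row0),
            min(self.col0, other.col0),
            max(self.row1, other.row1),
            max(self.col1, other.col1),
        )

    def inside(self, shape: tuple[int, int]) -> bool:
        return 0 <= self.row0 and 0 <= self.col0 and self.row1 <= shape[0] and self.col1 <= shape[1]


def _check_boxes_inside(boxes: Sequence[BBox], image_shape: tuple[int, int] | None) -> None:
    if image_shape is None:
        return
    for b in boxes:
        if not b.inside(image_shape):
            raise ValueError(f"box {b} lies outside image extent {image_shape}")


@dataclass(frozen=True)
class DetectionSet:
    """Ordered collection of detection boxes for one image."""

    boxes: tuple[BBox, ...]
    image_id: str = ""
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        _check_boxes_inside(self.boxes, self.image_shape)

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class GroundTruthSet:
    """Ordered collection of ground-truth boxes from one annotator (or the simulator)."""

    boxes: tuple[BBox, ...]
    annotator_id: str = ""
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        _check_boxes_inside(self.boxes, self.image_shape)

    def __len__(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    channel: int | None = None,
    page: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> Image2D:
    """Read a single-channel TIFF (or PNG fallback) losslessly.

    Multi-page TIFFs are treated as independent serial sections indexed
    from 0 via ``page``. A multi-channel image requires an explicit
    ``channel``; pixel size is taken from TIFF resolution metadata when
    present, otherwise ``pixel_size_nm`` is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            series_pages = tf.pages
            if page >= len(series_pages):
                raise IndexError(f"page {page} out of range for {path} ({len(series_pages)} pages)")
            tp = series_pages[page]
            arr = tp.asarray()
            res = _pixel_size_from_tiff(tp)
            if res is not None:
                pixel_size_nm = res
    else:
        from imageio.v3 import imread  # PNG fallback

        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {arr.shape[-1]} channels; select one with the channel option"
            )
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else 32
    return Image2D(pixels=arr, pixel_size_nm=pixel_size_nm, bit_depth=bit_depth)


def _pixel_size_from_tiff(page) -> float | None:
    """Pixel edge in nm from a TIFF page's XResolution, if meaningful."""
    try:
        num, den = page.tags["XResolution"].value
        if num == 0 or den == 0:
            return None
        unit_tag = page.tags.get("ResolutionUnit")
        unit_code = int(unit_tag.value) if unit_tag is not None else 0
        unit_nm = {2: 2.54e7, 3: 1.0e7}.get(unit_code)  # inch, cm
        if unit_nm is None:
            return None
        return unit_nm / (num / den)
    except (KeyError, TypeError, ZeroDivisionError):
        return None


def write_image(img: Image2D, path: str | Path) -> None:
    """Write an image as TIFF, preserving dtype (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(img.pixels))


# ---------------------------------------------------------------------------
# ImageJ ROI import
# ---------------------------------------------------------------------------
#
# Minimal reader for the binary .roi records written by ImageJ's ROI
# manager (and .zip archives of them). Only the geometry needed to form a
# tight bounding box is decoded: the header bounds for rectangle/oval
# ROIs and the vertex lists for polygon/freehand/traced ROIs. The byte
# layout follows ImageJ's RoiDecoder: big-endian, magic "Iout", type
# byte at offset 6, bounds as int16 at offsets 8-15, vertex count at 16,
# and relative int16 vertex coordinates from offset 64.

_ROI_MAGIC = b"Iout"
_ROI_POLYGON = 0
_ROI_RECT = 1
_ROI_OVAL = 2
_ROI_FREEHAND = 7
_ROI_TRACED = 8

_POLYGONAL_TYPES = {_ROI_POLYGON, _ROI_FREEHAND, _ROI_TRACED}


def _decode_roi(data: bytes, name: str = "") -> BBox | None:
    if len(data) < 64 or data[:4] != _ROI_MAGIC:
        raise ValueError(f"unparseable ImageJ ROI record {name!r}")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    if roi_type in (_ROI_RECT, _ROI_OVAL):
        return BBox(top, left, bottom, right)
    if roi_type in _POLYGONAL_TYPES:
        if n <= 0:
            return None
        end = 64 + 4 * n
        if len(data) < end:
            raise ValueError(f"truncated ROI record {name!r}")
        rel = np.frombuffer(data[64:end], dtype=">i2").reshape(2, n)
        xs = rel[0].astype(int) + left
        ys = rel[1].astype(int) + top
        return BBox(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    raise ValueError(f"unsupported ImageJ ROI type {roi_type} in {name!r}")


def read_imagej_rois(path: str | Path, image_shape: tuple[int, int]) -> GroundTruthSet:
    """Read an ImageJ ``.roi`` file or a ``.zip`` of ROIs as bounding boxes.

    Each freehand/polygon ROI is reduced to the tight axis-aligned
    bounding box of its outline, in 0-based half-open (row, col)
    coordinates. Boxes partially outside the image are clipped; ROIs
    fully outside the image are dropped with a warning.
    """
    path = Path(path)
    records: list[tuple[str, bytes]] = []
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if info.filename.lower().endswith(".roi"):
                    records.append((info.filename, zf.read(info)))
    else:
        records.append((path.name, path.read_bytes()))

    boxes: list[BBox] = []
    for name, data in records:
        box = _decode_roi(data, name)
        if box is None:
            continue
        clipped = _clip_box(box, image_shape)
        if clipped is None:
            logger.warning("ROI %r lies outside the image extent %s; dropped", name, image_shape)
            continue
        boxes.append(clipped)
    return GroundTruthSet(boxes=tuple(boxes), annotator_id=path.stem, image_shape=image_shape)


def _clip_box(box: BBox, shape: tuple[int, int]) -> BBox | None:
    r0, c0 = max(0, box.row0), max(0, box.col0)
    r1, c1 = min(shape[0], box.row1), min(shape[1], box.col1)
    if r1 <= r0 or c1 <= c0:
        return None
    return BBox(r0, c0, r1, c1, label=box.label)


def write_imagej_roi(box_or_vertices, path: str | Path | None = None) -> bytes:
    """Encode a rectangle BBox or an (N, 2) array of (row, col) polygon
    vertices as an ImageJ ``.roi`` record. Used for interop and for
    round-trip testing of the reader."""
    if isinstance(box_or_vertices, BBox):
        b = box_or_vertices
        header = bytearray(64)
        header[:4] = _ROI_MAGIC
        struct.pack_into(">h", header, 4, 227)  # version
        header[6] = _ROI_RECT
        struct.pack_into(">4h", header, 8, b.row0, b.col0, b.row1, b.col1)
        data = bytes(header)
    else:
        verts = np.asarray(box_or_vertices, dtype=int)
        ys, xs = verts[:, 0], verts[:, 1]
        top, left = int(ys.min()), int(xs.min())
        header = bytearray(64)
        header[:4] = _ROI_MAGIC
        struct.pack_into(">h", header, 4, 227)
        header[6] = _ROI_FREEHAND
        struct.pack_into(">4h", header, 8, top, left, int(ys.max()) + 1, int(xs.max()) + 1)
        struct.pack_into(">h", header, 16, len(verts))
        body = np.concatenate([xs - left, ys - top]).astype(">i2").tobytes()
        data = bytes(header) + body
    if path is not None:
        Path(path).write_bytes(data)
    return data


def write_imagej_roi_zip(rois: Iterable, path: str | Path) -> None:
    """Write several ROIs into an ImageJ-compatible ``.zip`` archive."""
    with zipfile.ZipFile(path, "w") as zf:
        for i, roi in enumerate(rois):
            zf.writestr(f"roi_{i:04d}.roi", write_imagej_roi(roi))


# ---------------------------------------------------------------------------
# Box tables
# ---------------------------------------------------------------------------

_BOX_COLUMNS = ["image_id", "row0", "col0", "row1", "col1", "label"]


def write_boxes(dets: DetectionSet | GroundTruthSet, path: str | Path, format: Literal["csv", "json"] = "csv") -> None:
    """Write one record per box (``image_id,row0,col0,row1,col1,label``).

    CSV output carries a header row; reading the file back with
    :func:`read_boxes` reproduces the box list exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image_id = dets.image_id if isinstance(dets, DetectionSet) else dets.annotator_id
    rows = [
        {"image_id": image_id, "row0": b.row0, "col0": b.col0, "row1": b.row1, "col1": b.col1,
         "label": -1 if b.label is None else b.label}
        for b in dets.boxes
    ]
    if format == "csv":
        pd.DataFrame(rows, columns=_BOX_COLUMNS).to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise ValueError(f"unknown box format {format!r}")


def read_boxes(path: str | Path, image_shape: tuple[int, int] | None = None) -> DetectionSet:
    """Read a CSV/JSON box table written by :func:`write_boxes`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows, columns=_BOX_COLUMNS)
    else:
        df = pd.read_csv(path)
    boxes = tuple(
        BBox(int(r.row0), int(r.col0), int(r.row1), int(r.col1),
             label=None if int(r.label) < 0 else int(r.label))
        for r in df.itertuples()
    )
    image_id = str(df["image_id"].iloc[0]) if len(df) else ""
    return DetectionSet(boxes=boxes, image_id=image_id, image_shape=image_shape)
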