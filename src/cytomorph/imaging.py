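"""Bright-field channel processing.

Background removal, mean-based binarization, connected-component blob
detection and the four BF morphometric features: area, perimeter
(Crofton estimate), aspect ratio (minimum-area rotated rectangle) and
cell count (distance-transform watershed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.segmentation import watershed

from .errors import InputError

__all__ = [
    "FramePair",
    "BackgroundModel",
    "BlobRecord",
    "subtract_background",
    "binarize_bf",
    "detect_blobs",
    "measure_area",
    "measure_perimeter",
    "measure_aspect_ratio",
    "estimate_cell_count_bf",
]

DEFAULT_AREA_FLOOR_UM2 = 10.0  # histograms and detection both start at 10 um^2
DEFAULT_SEED_SEPARATION_UM = 6.0


@dataclass
class FramePair:
    """One time point: BF and FL 8-bit views acquired simultaneously.

    ``registration_offset`` maps FL coordinates onto BF coordinates
    (``bf_pos = fl_pos + registration_offset``).
    """

    bf: np.ndarray
    fl: np.ndarray
    frame_index: int = 0
    frame_rate: float = 200.0
    registration_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.bf = np.asarray(self.bf)
        self.fl = np.asarray(self.fl)
        if self.bf.shape != self.fl.shape:
            raise InputError(
                f"BF and FL shapes differ: {self.bf.shape} vs {self.fl.shape}"
            )
        for name, arr in (("bf", self.bf), ("fl", self.fl)):
            if arr.ndim != 2:
                raise InputError(f"{name} view must be 2-D, got {arr.ndim}-D")
            if arr.min() < 0 or arr.max() > 255:
                raise InputError(f"{name} intensities outside [0, 255]")

    @property
    def timestamp(self) -> float:
        return self.frame_index / self.frame_rate


@dataclass
class BackgroundModel:
    """Pre-recorded per-channel background frames."""

    bf_background: np.ndarray
    fl_background: np.ndarray

    def __post_init__(self) -> None:
        self.bf_background = np.asarray(self.bf_background)
        self.fl_background = np.asarray(self.fl_background)
        if self.bf_background.shape != self.fl_background.shape:
            raise InputError("background channel shapes differ")

    @classmethod
    def flat(cls, shape: tuple[int, int], bf_level: float, fl_level: float) -> "BackgroundModel":
        return cls(
            bf_background=np.full(shape, bf_level, dtype=np.uint8),
            fl_background=np.full(shape, fl_level, dtype=np.uint8),
        )


@dataclass
class BlobRecord:
    """A detected BF particle and its morphometric features.

    The pixel mask is stored as a local boolean patch plus its bounding
    box (``bbox = (min_row, min_col, max_row, max_col)``, half-open).
    """

    blob_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area_um2: float = 0.0
    perimeter_um: float = 0.0
    aspect_ratio: float = 1.0
    cell_count_bf: int = 1

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def subtract_background(frame_channel: np.ndarray, background_channel: np.ndarray) -> np.ndarray:
    """Absolute per-pixel deviation of a frame from its pre-recorded background.

    The absolute value makes both darker (BF cells) and brighter
    (FL nuclei) object pixels register as positive deviations.
    """
    frame_channel = np.asarray(frame_channel)
    background_channel = np.asarray(background_channel)
    if frame_channel.shape != background_channel.shape:
        raise InputError(
            f"frame shape {frame_channel.shape} != background shape "
            f"{background_channel.shape}"
        )
    diff = frame_channel.astype(np.int16) - background_channel.astype(np.int16)
    return np.abs(diff).astype(np.float64)


def binarize_bf(diff_grid: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Threshold a background-subtracted BF grid at ``k`` times its mean.

    A pixel is foreground iff its value strictly exceeds
    ``k * mean(diff_grid)``.  An all-zero grid yields an empty mask.
    """
    diff_grid = np.asarray(diff_grid, dtype=np.float64)
    if diff_grid.size and diff_grid.min() < 0:
        raise InputError("diff grid must be nonnegative")
    threshold = k * diff_grid.mean() if diff_grid.size else 0.0
    return diff_grid > threshold


def detect_blobs(
    mask: np.ndarray,
    optics,
    area_floor_um2: float = DEFAULT_AREA_FLOOR_UM2,
    cell_count_params: dict | None = None,
) -> list[BlobRecord]:
    """Extract 8-connected components from a binary BF mask.

    Holes are filled before measurement; components smaller than
    ``area_floor_um2`` are discarded as noise.  Returned records carry
    all four BF morphometrics.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndi.binary_fill_holes(mask)
    labels = cc_label(filled, connectivity=2)
    px_area = optics.pixel_size**2
    min_px = int(math.ceil(area_floor_um2 / px_area))
    params = cell_count_params or {}
    records: list[BlobRecord] = []
    blob_id = 0
    counts = np.bincount(labels.ravel())
    for lab, slc in enumerate(ndi.find_objects(labels), start=1):
        if slc is None or counts[lab] < min_px:
            continue
        local = labels[slc] == lab
        rows, cols = np.nonzero(local)
        r0, c0 = slc[0].start, slc[1].start
        rec = BlobRecord(
            blob_id=blob_id,
            mask=local,
            bbox=(r0, c0, slc[0].stop, slc[1].stop),
            centroid=(r0 + float(rows.mean()), c0 + float(cols.mean())),
        )
        rec.area_um2 = measure_area(rec, optics)
        rec.perimeter_um = measure_perimeter(rec, optics)
        rec.aspect_ratio = measure_aspect_ratio(rec)
        rec.cell_count_bf = estimate_cell_count_bf(rec, optics, **params)
        records.append(rec)
        blob_id += 1
    return records


def measure_area(blob: BlobRecord, optics) -> float:
    """Blob area in um^2: foreground pixel count times pixel area."""
    n = int(np.count_nonzero(blob.mask))
    if n == 0:
        raise InputError("cannot measure area of an empty mask")
    return n * optics.pixel_size**2


def measure_perimeter(blob: BlobRecord, optics) -> float:
    """Perimeter in um via the 4-direction Crofton boundary estimate."""
    if not np.any(blob.mask):
        raise InputError("cannot measure perimeter of an empty mask")
    return float(perimeter_crofton(blob.mask, directions=4)) * optics.pixel_size


def _pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner coordinates of every foreground pixel (pixel = unit square)."""
    rows, cols = np.nonzero(mask)
    pts = np.empty((rows.size * 4, 2), dtype=np.float64)
    for i, (dr, dc) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        pts[i::4, 0] = rows + dr
        pts[i::4, 1] = cols + dc
    return pts


def measure_aspect_ratio(blob: BlobRecord) -> float:
    """Long side over short side of the minimum-area rotated bounding rectangle.

    Pixels are treated as unit squares (corner points), so an n x m
    axis-aligned rectangle of pixels measures exactly n x m.
    """
    if not np.any(blob.mask):
        raise InputError("cannot measure aspect ratio of an empty mask")
    pts = _pixel_corner_points(blob.mask)
    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except QhullError:  # degenerate input cannot occur for unit squares, but be safe
        hull_pts = pts
    best = math.inf
    best_dims = (1.0, 1.0)
    n = len(hull_pts)
    for i in range(n):
        edge = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = math.hypot(edge[0], edge[1])
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        proj_u = hull_pts @ u
        proj_v = hull_pts @ v
        w = proj_u.max() - proj_u.min()
        h = proj_v.max() - proj_v.min()
        if w * h < best:
            best = w * h
            best_dims = (w, h)
    long_side = max(best_dims)
    short_side = min(best_dims)
    return long_side / short_side if short_side > 0 else 1.0


def estimate_cell_count_bf(
    blob: BlobRecord,
    optics,
    min_seed_separation_um: float = DEFAULT_SEED_SEPARATION_UM,
    area_floor_um2: float = DEFAULT_AREA_FLOOR_UM2,
) -> int:
    """Number of constituent cells estimated from the BF mask alone.

    Local maxima of the Euclidean distance transform, at least
    ``min_seed_separation_um`` apart, seed a watershed; segments below
    the area floor are not counted.  Always at least 1.
    """
    mask = np.pad(np.asarray(blob.mask, dtype=bool), 1)
    if not mask.any():
        raise InputError("cannot count cells in an empty mask")
    dist = ndi.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(min_seed_separation_um / optics.pixel_size)))
    coords = peak_local_max(
        dist, min_distance=min_dist_px, labels=mask, exclude_border=False
    )
    if len(coords) <= 1:
        return 1
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    segments = watershed(-dist, markers=markers, mask=mask)
    min_px = area_floor_um2 / optics.pixel_size**2
    counts = np.bincount(segments.ravel())[1:]
    n = int(np.sum(counts >= min_px))
    return max(1, n)
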