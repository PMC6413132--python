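"""Fluorescence-channel processing and BF-FL position matching.

Nuclei are segmented from the background-subtracted FL view by a fixed
intensity floor (default 16 of 256, the 4-bit recognition level), then
assigned to BF blobs by centroid containment after applying the
registration offset between the two sensor halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .errors import InputError
from .imaging import BlobRecord

__all__ = [
    "NucleusRecord",
    "MatchResult",
    "binarize_fl",
    "detect_nuclei",
    "match_nuclei_to_blobs",
    "estimate_cells_from_nucleus_area",
]

DEFAULT_FL_FLOOR = 16  # of 256: lower 4 bits are noise, above is nucleus
DEFAULT_NUCLEUS_FLOOR_UM2 = 4.0
DEFAULT_MATCH_TOLERANCE_PX = 2
DEFAULT_REFERENCE_NUCLEUS_AREA_UM2 = 20.0


@dataclass
class NucleusRecord:
    """One segmented nucleus; centroid is in FL-view pixel coordinates."""

    nucleus_id: int
    area_um2: float
    centroid: tuple[float, float]
    parent_blob_id: int | None = None

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise InputError("nucleus area must be positive")


@dataclass
class MatchResult:
    """Nucleus count and total nucleus area assigned to one BF blob."""

    blob_id: int
    nucleus_count: int = 0
    nucleus_total_area_um2: float = 0.0
    nucleus_ids: list[int] = field(default_factory=list)


def binarize_fl(fl_diff_grid: np.ndarray, floor: float = DEFAULT_FL_FLOOR) -> np.ndarray:
    """Foreground iff the background-subtracted FL value strictly exceeds ``floor``."""
    return np.asarray(fl_diff_grid) > floor


def detect_nuclei(
    fl_mask: np.ndarray,
    optics,
    min_area_um2: float = DEFAULT_NUCLEUS_FLOOR_UM2,
) -> list[NucleusRecord]:
    """8-connected FL components, discarding specks below ``min_area_um2``."""
    labels = cc_label(np.asarray(fl_mask, dtype=bool), connectivity=2)
    px2 = optics.pixel_size**2
    out: list[NucleusRecord] = []
    nucleus_id = 0
    counts = np.bincount(labels.ravel())
    for lab, slc in enumerate(ndi.find_objects(labels), start=1):
        if slc is None:
            continue
        area = counts[lab] * px2
        if area < min_area_um2:
            continue
        rows, cols = np.nonzero(labels[slc] == lab)
        centroid = (slc[0].start + float(rows.mean()), slc[1].start + float(cols.mean()))
        out.append(NucleusRecord(nucleus_id=nucleus_id, area_um2=area, centroid=centroid))
        nucleus_id += 1
    return out


def match_nuclei_to_blobs(
    nuclei: list[NucleusRecord],
    blobs: list[BlobRecord],
    registration_offset: tuple[int, int] = (0, 0),
    tolerance_px: int = DEFAULT_MATCH_TOLERANCE_PX,
) -> list[MatchResult]:
    """Assign each nucleus to the blob containing its translated centroid.

    A nucleus matches a blob if its centroid, mapped into BF coordinates
    by ``registration_offset``, falls inside the blob mask dilated by
    ``tolerance_px`` (Chebyshev).  Ties go to the blob whose mask pixel
    is nearest.  Every blob gets a MatchResult; unmatched nuclei keep
    ``parent_blob_id = None``.
    """
    results = {b.blob_id: MatchResult(blob_id=b.blob_id) for b in blobs}
    d_row, d_col = registration_offset
    for nuc in nuclei:
        r = nuc.centroid[0] + d_row
        c = nuc.centroid[1] + d_col
        best_id: int | None = None
        best_dist = math.inf
        for blob in blobs:
            r0, c0, r1, c1 = blob.bbox
            if not (r0 - tolerance_px <= r < r1 + tolerance_px and c0 - tolerance_px <= c < c1 + tolerance_px):
                continue
            rows, cols = np.nonzero(blob.mask)
            d = np.max(
                np.stack([np.abs(rows + r0 - r), np.abs(cols + c0 - c)]), axis=0
            ).min()
            if d <= tolerance_px + 0.5 and d < best_dist:
                best_dist = d
                best_id = blob.blob_id
        if best_id is not None:
            nuc.parent_blob_id = best_id
            res = results[best_id]
            res.nucleus_count += 1
            res.nucleus_total_area_um2 += nuc.area_um2
            res.nucleus_ids.append(nuc.nucleus_id)
        else:
            nuc.parent_blob_id = None
    return list(results.values())


def estimate_cells_from_nucleus_area(
    nucleus_total_area_um2: float,
    reference_area_um2: float = DEFAULT_REFERENCE_NUCLEUS_AREA_UM2,
) -> int:
    """Cell count from total nucleus area and a typical single-nucleus area.

    Nearest integer of ``total / reference``, floored at 1 for any
    positive total; 0 only for an exactly zero total.
    """
    if reference_area_um2 <= 0:
        raise InputError("reference nucleus area must be positive")
    if nucleus_total_area_um2 < 0:
        raise InputError("nucleus area cannot be negative")
    if nucleus_total_area_um2 == 0:
        return 0
    return max(1, int(round(nucleus_total_area_um2 / reference_area_um2)))
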