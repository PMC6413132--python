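"""Shared test helpers: blob construction from raw masks, disk rasters."""

import math

import numpy as np

from cytomorph.imaging import BlobRecord


def make_blob(mask: np.ndarray, blob_id: int = 0) -> BlobRecord:
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size:
        r0, c0, r1, c1 = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
        local = mask[r0:r1, c0:c1]
        centroid = (float(rows.mean()), float(cols.mean()))
    else:
        r0 = c0 = 0
        r1 = c1 = 1
        local = np.zeros((1, 1), dtype=bool)
        centroid = (0.0, 0.0)
    return BlobRecord(
        blob_id=blob_id, mask=local, bbox=(int(r0), int(c0), int(r1), int(c1)), centroid=centroid
    )


def disk_mask(radius_px: float, pad: int = 3, center=(0.0, 0.0)) -> np.ndarray:
    half = int(math.ceil(radius_px + max(abs(center[0]), abs(center[1])))) + pad
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
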