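"""File formats: combined dual-view TIFF stacks, CSV tables, JSON summaries.

A stored frame is one 8-bit page per time point with the BF view on the
left half and the FL view on the right half, exactly as acquired on a
split sensor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .imaging import FramePair

__all__ = [
    "combine_views",
    "split_views",
    "write_frames",
    "read_frames",
    "write_background",
    "read_background",
    "write_masks",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]

OBJECT_COLUMNS = [
    "object_id",
    "frame",
    "area_um2",
    "perimeter_um",
    "aspect_ratio",
    "cell_count_bf",
    "nucleus_count",
    "nucleus_total_area_um2",
    "centroid_row",
    "centroid_col",
    "label",
]


def combine_views(bf: np.ndarray, fl: np.ndarray) -> np.ndarray:
    """Stitch BF (left) and FL (right) into one combined page."""
    if bf.shape != fl.shape:
        raise InputError("BF and FL views must have identical shapes")
    return np.hstack([bf, fl])


def split_views(page: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undo :func:`combine_views`; the page width must be even."""
    if page.ndim != 2 or page.shape[1] % 2:
        raise InputError(f"combined page must be 2-D with even width, got {page.shape}")
    half = page.shape[1] // 2
    return page[:, :half], page[:, half:]


def write_frames(path, frames: list[FramePair]) -> None:
    stack = np.stack([combine_views(f.bf, f.fl) for f in frames])
    tifffile.imwrite(path, stack.astype(np.uint8))


def read_frames(
    path,
    frame_rate: float = 200.0,
    registration_offset: tuple[int, int] = (0, 0),
) -> list[FramePair]:
    try:
        stack = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise InputError(f"cannot read frame stack {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    frames = []
    for i, page in enumerate(stack):
        bf, fl = split_views(page)
        frames.append(
            FramePair(
                bf=bf, fl=fl, frame_index=i,
                frame_rate=frame_rate, registration_offset=registration_offset,
            )
        )
    return frames


def write_background(path, bf_background: np.ndarray, fl_background: np.ndarray) -> None:
    tifffile.imwrite(path, combine_views(bf_background, fl_background).astype(np.uint8))


def read_background(path) -> tuple[np.ndarray, np.ndarray]:
    try:
        page = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise InputError(f"cannot read background {path}: {exc}") from exc
    return split_views(np.asarray(page))


def write_masks(path, masks: list[np.ndarray]) -> None:
    tifffile.imwrite(path, np.stack(masks).astype(np.uint32))


def write_table(path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
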