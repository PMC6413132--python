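"""End-to-end frame analysis: BF blobs + FL nuclei -> measured objects."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .config import RunConfig
from .imaging import BackgroundModel, FramePair, binarize_bf, detect_blobs, subtract_background
from .nuclei import binarize_fl, detect_nuclei, match_nuclei_to_blobs
from .sorter import ObjectRecord

__all__ = ["analyze_frame_pair", "analyze_frames", "records_to_table", "attach_ground_truth"]

logger = logging.getLogger("cytomorph.pipeline")


def analyze_frame_pair(
    pair: FramePair,
    background: BackgroundModel,
    config: RunConfig,
    id_offset: int = 0,
) -> list[ObjectRecord]:
    """Measure every particle in one frame pair.

    Order of operations: background removal on both channels, mean-based
    BF binarization, blob detection and BF morphometrics, FL floor
    binarization, nucleus detection, then position matching.
    """
    thr = config.thresholds
    optics = config.optics
    bf_diff = subtract_background(pair.bf, background.bf_background)
    bf_mask = binarize_bf(bf_diff, k=thr.bf_k)
    blobs = detect_blobs(
        bf_mask,
        optics,
        area_floor_um2=thr.area_floor_um2,
        cell_count_params={
            "min_seed_separation_um": thr.min_seed_separation_um,
            "area_floor_um2": thr.area_floor_um2,
        },
    )
    fl_diff = subtract_background(pair.fl, background.fl_background)
    fl_mask = binarize_fl(fl_diff, floor=thr.fl_floor)
    nuclei = detect_nuclei(fl_mask, optics, min_area_um2=thr.nucleus_floor_um2)
    matches = match_nuclei_to_blobs(
        nuclei, blobs, pair.registration_offset, tolerance_px=thr.match_tolerance_px
    )
    by_blob = {m.blob_id: m for m in matches}
    records = []
    for blob in blobs:
        m = by_blob[blob.blob_id]
        records.append(
            ObjectRecord(
                object_id=id_offset + blob.blob_id,
                frame_index=pair.frame_index,
                area_um2=blob.area_um2,
                perimeter_um=blob.perimeter_um,
                aspect_ratio=blob.aspect_ratio,
                cell_count_bf=blob.cell_count_bf,
                nucleus_count=m.nucleus_count,
                nucleus_total_area_um2=m.nucleus_total_area_um2,
                centroid=blob.centroid,
            )
        )
    return records


def analyze_frames(
    frames,
    background: BackgroundModel,
    config: RunConfig,
) -> tuple[list[ObjectRecord], list[dict]]:
    """Run :func:`analyze_frame_pair` over a frame iterable with a per-frame log."""
    records: list[ObjectRecord] = []
    frame_log: list[dict] = []
    next_id = 0
    for pair in frames:
        t0 = time.perf_counter()
        found = analyze_frame_pair(pair, background, config, id_offset=next_id)
        latency_ms = 1000.0 * (time.perf_counter() - t0)
        next_id += len(found)
        records.extend(found)
        frame_log.append(
            {"frame": pair.frame_index, "n_objects": len(found), "latency_ms": latency_ms}
        )
        logger.info(
            "frame=%d objects=%d latency_ms=%.2f", pair.frame_index, len(found), latency_ms
        )
    return records, frame_log


def run_synthetic_analysis(
    config: RunConfig,
    kind: str = "positive",
    day: int = 11,
    n_objects: int = 20_000,
    seed: int | None = None,
    classify_records: bool = True,
) -> tuple[list[ObjectRecord], pd.DataFrame]:
    """Generate a synthetic stream and push it through the full pipeline.

    Frames are streamed (never all held in memory); the frame budget is
    sized so the expected object count matches ``n_objects``.  Records
    get ground-truth labels attached and, optionally, classifier labels.
    """
    import math

    from .imaging import BackgroundModel
    from .sorter import classify
    from .synthgen import default_population, iter_stream

    seed = config.seed if seed is None else seed
    pop = default_population(kind, day)
    rate = config.stream.arrival_rate
    if rate <= 0:
        raise ValueError("arrival_rate must be positive for a synthetic run")
    n_frames = max(1, math.ceil(n_objects / rate))
    background = BackgroundModel.flat(
        (config.optics.frame_height, config.optics.frame_width),
        config.optics.bf_background_level,
        config.optics.fl_background_level,
    )
    records: list[ObjectRecord] = []
    truth_rows: list[dict] = []
    next_id = 0
    for pair, rows, _mask in iter_stream(
        pop, config.optics, config.stream, n_frames, seed,
        registration_offset=config.registration_offset,
    ):
        found = analyze_frame_pair(pair, background, config, id_offset=next_id)
        next_id += len(found)
        records.extend(found)
        truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows)
    attach_ground_truth(records, truth)
    if classify_records:
        for rec in records:
            rec.label = classify(rec, config.rules)
    return records, truth


def records_to_table(records: list[ObjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "object_id": r.object_id,
            "frame": r.frame_index,
            "area_um2": r.area_um2,
            "perimeter_um": r.perimeter_um,
            "aspect_ratio": r.aspect_ratio,
            "cell_count_bf": r.cell_count_bf,
            "nucleus_count": r.nucleus_count,
            "nucleus_total_area_um2": r.nucleus_total_area_um2,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "label": r.label,
            "true_label": r.true_label,
        }
        for r in records
    ]
    columns = [
        "object_id", "frame", "area_um2", "perimeter_um", "aspect_ratio",
        "cell_count_bf", "nucleus_count", "nucleus_total_area_um2",
        "centroid_row", "centroid_col", "label", "true_label",
    ]
    return pd.DataFrame(rows, columns=columns)


def table_to_records(table: pd.DataFrame) -> list[ObjectRecord]:
    records = []
    for row in table.itertuples(index=False):
        label = getattr(row, "label", None)
        true_label = getattr(row, "true_label", None)
        records.append(
            ObjectRecord(
                object_id=int(row.object_id),
                frame_index=int(row.frame),
                area_um2=float(row.area_um2),
                perimeter_um=float(row.perimeter_um),
                aspect_ratio=float(row.aspect_ratio),
                cell_count_bf=int(row.cell_count_bf),
                nucleus_count=int(row.nucleus_count),
                nucleus_total_area_um2=float(row.nucleus_total_area_um2),
                centroid=(float(row.centroid_row), float(row.centroid_col)),
                label=None if pd.isna(label) else str(label),
                true_label=None if pd.isna(true_label) else str(true_label),
            )
        )
    return records


def attach_ground_truth(
    records: list[ObjectRecord],
    truth: pd.DataFrame,
    max_dist_px: float = 5.0,
) -> int:
    """Assign each record the nearest same-frame ground-truth label.

    Returns the number of records matched.  Unmatched records keep
    ``true_label = None``.
    """
    matched = 0
    by_frame = {frame: grp for frame, grp in truth.groupby("frame")}
    for rec in records:
        grp = by_frame.get(rec.frame_index)
        if grp is None or grp.empty:
            continue
        d = np.hypot(
            grp["centroid_row"].to_numpy() - rec.centroid[0],
            grp["centroid_col"].to_numpy() - rec.centroid[1],
        )
        i = int(np.argmin(d))
        if d[i] <= max_dist_px:
            rec.true_label = str(grp.iloc[i]["label"])
            matched += 1
    return matched
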