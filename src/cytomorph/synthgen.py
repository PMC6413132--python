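"""Synthetic paired BF/FL frame generator with exact ground truth.

Objects are disks (single cells, debris) or chains of overlapping disks
(clusters) drifting along a hydrodynamically focused lane; nuclei are
smaller disks rendered only in the FL view, at the same coordinates as
their parent cell.  Shapes are rasterized once, in local coordinates, so
the recorded ground truth is exact for the rendered masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, PlacementError
from .imaging import FramePair

__all__ = [
    "OpticsModel",
    "PopulationComponent",
    "PopulationModel",
    "StreamModel",
    "GroundTruthObject",
    "sample_object",
    "render_frame_pair",
    "generate_stream",
    "iter_stream",
    "default_population",
    "GROUND_TRUTH_COLUMNS",
]

LABELS = ("debris", "rbc_debris", "wbc", "large_single", "cluster")

# Center spacing of adjacent disks in a cluster chain, as a multiple of
# the disk radius.  1.6 keeps adjacent disks overlapping while leaving
# non-adjacent disks disjoint, so the union area has a closed form.
CHAIN_SPACING_FACTOR = 1.6
# Pairwise lens area / r^2 for two unit-radius disks at distance 1.6 r.
_C = CHAIN_SPACING_FACTOR
CHAIN_OVERLAP_COEF = 2.0 * math.acos(_C / 2.0) - (_C / 2.0) * math.sqrt(4.0 - _C * _C)

GROUND_TRUTH_COLUMNS = [
    "object_id",
    "frame",
    "label",
    "area_um2",
    "cell_count",
    "nucleus_count",
    "nucleus_total_area_um2",
    "centroid_row",
    "centroid_col",
]


@dataclass(frozen=True)
class OpticsModel:
    """Rendering geometry and intensity model of the dual-view camera."""

    pixel_size: float = 0.5  # um per pixel
    frame_width: int = 256  # pixels per channel view
    frame_height: int = 120
    bf_background_level: float = 200.0
    fl_background_level: float = 8.0
    bf_contrast: float = 60.0  # object intensity offset below BF background
    fl_nucleus_peak: float = 80.0  # nucleus intensity offset above FL background
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.frame_width < 1 or self.frame_height < 1:
            raise ConfigError("frame dimensions must be positive")
        for name in ("bf_background_level", "fl_background_level", "bf_contrast", "fl_nucleus_peak"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigError(f"{name}={v} outside [0, 255]")
        # nuclei must clear the 16/256 FL recognition floor
        if self.fl_nucleus_peak <= 16:
            raise ConfigError("fl_nucleus_peak must exceed 16 (4-bit FL floor)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class PopulationComponent:
    """One mixture component: a particle class and its size distributions.

    Areas are lognormal (``area_median_um2``, ``area_log_sd``) truncated
    to ``area_support``; nucleus areas are normal, clipped at 8 um^2.
    """

    label: str
    weight: float
    area_median_um2: float
    area_log_sd: float
    area_support: tuple[float, float]
    cell_count_choices: tuple[int, ...] = (1,)
    cell_count_probs: tuple[float, ...] = (1.0,)
    nuclei_per_cell: int = 1
    nucleus_area_mean_um2: float = 20.0
    nucleus_area_sd_um2: float = 4.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ConfigError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.weight < 0:
            raise ConfigError("component weight must be nonnegative")
        lo, hi = self.area_support
        if not (0 < lo < hi <= 1000):
            raise ConfigError("area support must lie within (0, 1000] um^2")
        if self.area_median_um2 <= 0 or self.area_log_sd < 0:
            raise ConfigError("invalid area distribution parameters")
        if len(self.cell_count_choices) != len(self.cell_count_probs):
            raise ConfigError("cell_count choices and probs length mismatch")
        if abs(sum(self.cell_count_probs) - 1.0) > 1e-9:
            raise ConfigError("cell_count_probs must sum to 1")
        if self.label in ("debris", "rbc_debris") and self.nuclei_per_cell != 0:
            raise ConfigError("debris components must have 0 nuclei per cell")
        if self.label not in ("debris", "rbc_debris") and self.nuclei_per_cell < 1:
            raise ConfigError("nucleated components need >= 1 nucleus per cell")


@dataclass(frozen=True)
class PopulationModel:
    """A weighted mixture of particle components, tagged with a study day."""

    components: tuple[PopulationComponent, ...]
    day: int = 11

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigError("population needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"component weights sum to {total}, expected 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


@dataclass(frozen=True)
class StreamModel:
    """Flow and acquisition parameters of the virtual channel."""

    frame_rate: float = 200.0  # fps
    arrival_rate: float = 2.0  # expected objects per frame (Poisson)
    lane_center: int = 60  # pixel row of the focused sample lane
    lane_jitter_sd: float = 2.0  # um
    flow_speed: float = 3.0  # mm/s, metadata only
    channel_width: float = 50.0  # um
    channel_height: float = 22.0  # um, metadata only
    min_spacing_um: float = 20.0  # minimum center gap between neighbours

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.arrival_rate < 0:
            raise ConfigError("arrival_rate must be nonnegative")
        if self.lane_center < 0:
            raise ConfigError("lane_center must be nonnegative")


@dataclass(frozen=True)
class Disk:
    """A disk in object-local coordinates (um offsets from the centroid)."""

    row_um: float
    col_um: float
    radius_um: float


@dataclass
class GroundTruthObject:
    """One synthetic particle with exact rendered-mask ground truth."""

    object_id: int
    label: str
    true_area_um2: float
    true_cell_count: int
    true_nucleus_count: int
    true_nucleus_total_area_um2: float
    cells: tuple[Disk, ...]
    nuclei: tuple[Disk, ...]
    cell_mask: np.ndarray  # local odd-sized boolean patch, centroid at center
    nucleus_mask: np.ndarray  # same grid; subset of cell_mask
    target_area_um2: float  # area drawn from the component distribution
    centroid: tuple[int, int] | None = None  # assigned at placement (pixels)

    @property
    def half_extent_px(self) -> int:
        return (self.cell_mask.shape[0] - 1) // 2


def _truncated_lognormal(rng, median: float, log_sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = median * math.exp(log_sd * rng.standard_normal())
        if lo <= v < hi:
            return v
    raise ConfigError(
        f"area distribution (median={median}, log_sd={log_sd}) "
        f"rarely hits support [{lo}, {hi})"
    )


def _chain_radius(total_area: float, n_cells: int) -> float:
    """Disk radius so a straight chain of n overlapping disks has the given union area."""
    denom = n_cells * math.pi - (n_cells - 1) * CHAIN_OVERLAP_COEF
    return math.sqrt(total_area / denom)


def _rasterize(disks: tuple[Disk, ...], pixel_size: float, half: int) -> np.ndarray:
    n = 2 * half + 1
    coords = (np.arange(n) - half) * pixel_size
    yy = coords[:, None]
    xx = coords[None, :]
    mask = np.zeros((n, n), dtype=bool)
    for d in disks:
        mask |= (yy - d.row_um) ** 2 + (xx - d.col_um) ** 2 <= d.radius_um**2
    return mask


def sample_object(pop: PopulationModel, rng: np.random.Generator, object_id: int = 0) -> GroundTruthObject:
    """Draw one particle from the mixture and rasterize its geometry.

    Cluster geometry is a straight chain of ``cell_count`` overlapping
    disks whose analytic union area equals the drawn area; each cell of
    a nucleated component carries ``nuclei_per_cell`` nucleus disks kept
    fully inside the cell.
    """
    idx = int(rng.choice(len(pop.components), p=pop.weights))
    comp = pop.components[idx]
    lo, hi = comp.area_support
    area = _truncated_lognormal(rng, comp.area_median_um2, comp.area_log_sd, lo, hi)
    k = int(rng.choice(comp.cell_count_choices, p=comp.cell_count_probs))

    if k == 1:
        r = math.sqrt(area / math.pi)
        cells = (Disk(0.0, 0.0, r),)
    else:
        r = _chain_radius(area, k)
        spacing = CHAIN_SPACING_FACTOR * r
        theta = rng.uniform(0.0, math.pi)
        dy, dx = math.sin(theta), math.cos(theta)
        offs = (np.arange(k) - (k - 1) / 2.0) * spacing
        cells = tuple(Disk(o * dy, o * dx, r) for o in offs)

    nuclei: list[Disk] = []
    for cell in cells:
        for _ in range(comp.nuclei_per_cell):
            a = max(8.0, rng.normal(comp.nucleus_area_mean_um2, comp.nucleus_area_sd_um2))
            rn = min(math.sqrt(a / math.pi), 0.7 * cell.radius_um)
            # jitter inside the cell, never past the membrane
            slack = max(0.0, cell.radius_um - rn)
            rho = 0.3 * slack * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            nuclei.append(
                Disk(cell.row_um + rho * math.sin(phi), cell.col_um + rho * math.cos(phi), rn)
            )

    return _finalize_object(object_id, comp.label, area, k, cells, tuple(nuclei), pixel_size=0.5)


def _finalize_object(
    object_id: int,
    label: str,
    target_area: float,
    cell_count: int,
    cells: tuple[Disk, ...],
    nuclei: tuple[Disk, ...],
    pixel_size: float,
) -> GroundTruthObject:
    extent = max(math.hypot(d.row_um, d.col_um) + d.radius_um for d in cells)
    half = int(math.ceil(extent / pixel_size)) + 1
    cell_mask = _rasterize(cells, pixel_size, half)
    if nuclei:
        nucleus_mask = _rasterize(nuclei, pixel_size, half) & cell_mask
    else:
        nucleus_mask = np.zeros_like(cell_mask)
    px2 = pixel_size**2
    return GroundTruthObject(
        object_id=object_id,
        label=label,
        true_area_um2=float(cell_mask.sum()) * px2,
        true_cell_count=cell_count,
        true_nucleus_count=len(nuclei),
        true_nucleus_total_area_um2=float(nucleus_mask.sum()) * px2,
        cells=cells,
        nuclei=nuclei,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        target_area_um2=target_area,
    )


def sample_object_with_optics(
    pop: PopulationModel, optics: OpticsModel, rng: np.random.Generator, object_id: int = 0
) -> GroundTruthObject:
    """As :func:`sample_object` but rasterized at the optics' pixel size."""
    obj = sample_object(pop, rng, object_id)
    if optics.pixel_size == 0.5:
        return obj
    return _finalize_object(
        obj.object_id, obj.label, obj.target_area_um2, obj.true_cell_count,
        obj.cells, obj.nuclei, optics.pixel_size,
    )


def _paste(canvas: np.ndarray, patch: np.ndarray, center: tuple[int, int], delta: float) -> None:
    half = (patch.shape[0] - 1) // 2
    r0, c0 = center[0] - half, center[1] - half
    r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
    if r0 < 0 or c0 < 0 or r1 > canvas.shape[0] or c1 > canvas.shape[1]:
        raise PlacementError(
            f"object patch at {center} extends outside the {canvas.shape} view"
        )
    canvas[r0:r1, c0:c1][patch] += delta


def render_frame_pair(
    objects: list[GroundTruthObject],
    optics: OpticsModel,
    stream: StreamModel,
    rng: np.random.Generator,
    frame_index: int = 0,
    registration_offset: tuple[int, int] = (0, 0),
    check_spacing: bool = True,
) -> tuple[FramePair, list[dict], np.ndarray]:
    """Render placed objects into one BF/FL frame pair.

    Returns the frame pair, one ground-truth row per object and a label
    mask (pixel value = object_id + 1).  Objects must carry integer
    centroids; the FL nuclei are drawn at the BF coordinates minus the
    registration offset, so the analysis side can map them back.
    """
    shape = (optics.frame_height, optics.frame_width)
    bf = np.full(shape, optics.bf_background_level, dtype=np.float64)
    fl = np.full(shape, optics.fl_background_level, dtype=np.float64)
    label_mask = np.zeros(shape, dtype=np.uint32)
    d_row, d_col = registration_offset

    if check_spacing and len(objects) > 1:
        for i in range(len(objects)):
            for j in range(i + 1, len(objects)):
                ci, cj = objects[i].centroid, objects[j].centroid
                gap = math.hypot(ci[0] - cj[0], ci[1] - cj[1]) * optics.pixel_size
                if gap < stream.min_spacing_um:
                    raise PlacementError(
                        f"objects {objects[i].object_id} and {objects[j].object_id} "
                        f"are {gap:.1f} um apart (< {stream.min_spacing_um} um)"
                    )

    rows: list[dict] = []
    for obj in objects:
        if obj.centroid is None:
            raise PlacementError(f"object {obj.object_id} has no placement")
        r, c = obj.centroid
        _paste(bf, obj.cell_mask, (r, c), -optics.bf_contrast)
        if obj.nucleus_mask.any():
            _paste(fl, obj.nucleus_mask, (r - d_row, c - d_col), optics.fl_nucleus_peak)
        half = obj.half_extent_px
        region = label_mask[r - half : r + half + 1, c - half : c + half + 1]
        region[obj.cell_mask] = obj.object_id + 1
        rows.append(
            {
                "object_id": obj.object_id,
                "frame": frame_index,
                "label": obj.label,
                "area_um2": obj.true_area_um2,
                "cell_count": obj.true_cell_count,
                "nucleus_count": obj.true_nucleus_count,
                "nucleus_total_area_um2": obj.true_nucleus_total_area_um2,
                "centroid_row": r,
                "centroid_col": c,
            }
        )

    if optics.noise_sd > 0:
        bf += rng.normal(0.0, optics.noise_sd, shape)
        fl += rng.normal(0.0, optics.noise_sd, shape)
    pair = FramePair(
        bf=np.clip(np.rint(bf), 0, 255).astype(np.uint8),
        fl=np.clip(np.rint(fl), 0, 255).astype(np.uint8),
        frame_index=frame_index,
        frame_rate=stream.frame_rate,
        registration_offset=registration_offset,
    )
    return pair, rows, label_mask


def _place_objects(
    objects: list[GroundTruthObject],
    optics: OpticsModel,
    stream: StreamModel,
    rng: np.random.Generator,
) -> list[GroundTruthObject]:
    """Assign lane-centered, spaced integer centroids; drops objects that cannot fit."""
    px = optics.pixel_size
    jitter_px = stream.lane_jitter_sd / px
    placed: list[GroundTruthObject] = []
    kept = list(objects)
    while kept:
        ok = False
        for _ in range(100):
            cols = []
            rows_ = []
            feasible = True
            for obj in kept:
                margin = obj.half_extent_px + 1
                if 2 * margin + 1 > min(optics.frame_width, optics.frame_height):
                    raise PlacementError(
                        f"object {obj.object_id} ({2 * margin + 1} px) exceeds the view"
                    )
                col = int(rng.integers(margin, optics.frame_width - margin))
                row = int(round(stream.lane_center + jitter_px * rng.standard_normal()))
                row = min(max(row, margin), optics.frame_height - margin - 1)
                cols.append(col)
                rows_.append(row)
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    gap_um = math.hypot(rows_[i] - rows_[j], cols[i] - cols[j]) * px
                    need = max(
                        stream.min_spacing_um,
                        (kept[i].half_extent_px + kept[j].half_extent_px + 2) * px,
                    )
                    if gap_um < need:
                        feasible = False
                        break
                if not feasible:
                    break
            if feasible:
                for obj, r, c in zip(kept, rows_, cols):
                    obj.centroid = (r, c)
                placed = kept
                ok = True
                break
        if ok:
            break
        kept = kept[:-1]  # too crowded: thin the frame and retry
    return placed


def iter_stream(
    pop: PopulationModel,
    optics: OpticsModel,
    stream: StreamModel,
    n_frames: int,
    seed: int,
    registration_offset: tuple[int, int] = (0, 0),
):
    """Yield ``(FramePair, ground_truth_rows, label_mask)`` for each frame."""
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    next_id = 0
    for frame_index in range(n_frames):
        n_obj = int(rng.poisson(stream.arrival_rate))
        objs = []
        for _ in range(n_obj):
            objs.append(sample_object_with_optics(pop, optics, rng, object_id=next_id))
            next_id += 1
        objs = _place_objects(objs, optics, stream, rng)
        yield render_frame_pair(
            objs, optics, stream, rng,
            frame_index=frame_index,
            registration_offset=registration_offset,
            check_spacing=False,  # placement already enforced spacing
        )


def generate_stream(
    pop: PopulationModel,
    optics: OpticsModel,
    stream: StreamModel,
    n_frames: int,
    seed: int,
    registration_offset: tuple[int, int] = (0, 0),
) -> tuple[list[FramePair], pd.DataFrame, list[np.ndarray]]:
    """Materialize a full frame sequence plus its ground-truth table."""
    frames: list[FramePair] = []
    rows: list[dict] = []
    masks: list[np.ndarray] = []
    for pair, frame_rows, mask in iter_stream(
        pop, optics, stream, n_frames, seed, registration_offset
    ):
        frames.append(pair)
        rows.extend(frame_rows)
        masks.append(mask)
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return frames, truth, masks


# Mixture weights below are calibrated fixtures, not measured values: the
# source material gives size bands and a qualitative time course only.
_POSITIVE_EXTRA = {2: (0.008, 0.0), 4: (0.02, 0.004), 7: (0.04, 0.01), 9: (0.06, 0.015), 11: (0.08, 0.02)}


def _base_components() -> list[PopulationComponent]:
    return [
        PopulationComponent(
            label="rbc_debris", weight=0.45, area_median_um2=18.0, area_log_sd=0.25,
            area_support=(12.0, 30.0), nuclei_per_cell=0,
        ),
        PopulationComponent(
            label="wbc", weight=0.50, area_median_um2=60.0, area_log_sd=0.09,
            area_support=(50.0, 70.0), nucleus_area_mean_um2=20.0, nucleus_area_sd_um2=4.0,
        ),
        PopulationComponent(
            label="debris", weight=0.05, area_median_um2=50.0, area_log_sd=0.40,
            area_support=(30.0, 270.0), nuclei_per_cell=0,
            cell_count_choices=(1, 2, 3), cell_count_probs=(0.6, 0.3, 0.1),
        ),
    ]


def default_population(kind: str = "control", day: int = 11) -> PopulationModel:
    """Built-in mixtures: ``control`` or ``positive`` at a study day (2,4,7,9,11)."""
    if day not in (2, 4, 7, 9, 11):
        raise ConfigError(f"day must be one of 2, 4, 7, 9, 11; got {day}")
    base = _base_components()
    if kind == "control":
        return PopulationModel(components=tuple(base), day=day)
    if kind != "positive":
        raise ConfigError(f"unknown population kind {kind!r}")
    ls_w, cl_w = _POSITIVE_EXTRA[day]
    scale = 1.0 - ls_w - cl_w
    comps = [replace(c, weight=c.weight * scale) for c in base]
    if ls_w > 0:
        comps.append(
            PopulationComponent(
                label="large_single", weight=ls_w, area_median_um2=125.0,
                area_log_sd=0.11, area_support=(90.0, 150.0),
                nucleus_area_mean_um2=30.0, nucleus_area_sd_um2=6.0,
            )
        )
    if cl_w > 0:
        comps.append(
            PopulationComponent(
                label="cluster", weight=cl_w, area_median_um2=210.0,
                area_log_sd=0.3, area_support=(150.0, 900.0),
                cell_count_choices=(2, 3, 4, 5, 6),
                cell_count_probs=(0.35, 0.25, 0.2, 0.12, 0.08),
                nucleus_area_mean_um2=20.0, nucleus_area_sd_um2=4.0,
            )
        )
    total = sum(c.weight for c in comps)
    comps = [replace(c, weight=c.weight / total) for c in comps]
    return PopulationModel(components=tuple(comps), day=day)
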