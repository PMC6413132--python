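"""Rule-based classification, sort trigger, pulse and outlet routing.

The area bands, the 300-um^2 trigger and the 8.3-um routing threshold
are the decision contract of the virtual sorter; both decision
boundaries are strict inequalities ("exceeded", "more than").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, InputError

__all__ = [
    "ObjectRecord",
    "BandRuleSet",
    "ChannelGeometry",
    "SortPulse",
    "SortEvent",
    "classify",
    "trigger_sort",
    "apply_pulse",
    "route_outlet",
    "run_sorting",
    "LABEL_SET",
    "DEFAULT_TRIGGER_AREA_UM2",
]

LABEL_SET = (
    "rbc_debris",
    "unclassified_small",
    "wbc",
    "intermediate",
    "large_single",
    "cluster_2plus",
    "cluster_3plus",
    "debris",
)

DEFAULT_TRIGGER_AREA_UM2 = 300.0
DEFAULT_TARGET_LABELS = ("cluster",)


@dataclass
class ObjectRecord:
    """A fully measured particle: BF morphometrics plus FL nucleus features."""

    object_id: int
    frame_index: int
    area_um2: float
    perimeter_um: float
    aspect_ratio: float
    cell_count_bf: int
    nucleus_count: int
    nucleus_total_area_um2: float
    centroid: tuple[float, float] = (0.0, 0.0)
    label: str | None = None
    true_label: str | None = None  # ground truth, when available

    def __post_init__(self) -> None:
        if self.nucleus_count < 0:
            raise InputError("nucleus_count cannot be negative")


@dataclass(frozen=True)
class BandRuleSet:
    """Area bands (um^2, half-open [lo, hi)) plus nucleus-consistency switches.

    Cluster bands demand corroborating nuclei; large area without nuclei
    is debris, and with too few nuclei it is downgraded.
    """

    rbc_debris_band: tuple[float, float] = (10.0, 30.0)
    unclassified_small_band: tuple[float, float] = (30.0, 50.0)
    wbc_band: tuple[float, float] = (50.0, 70.0)
    intermediate_band: tuple[float, float] = (70.0, 90.0)
    large_single_band: tuple[float, float] = (90.0, 150.0)
    cluster_2plus_band: tuple[float, float] = (150.0, 270.0)
    cluster_3plus_min: float = 270.0
    require_nucleus_consistency: bool = True

    def bands(self) -> list[tuple[str, float, float]]:
        out = [
            ("rbc_debris", *self.rbc_debris_band),
            ("unclassified_small", *self.unclassified_small_band),
            ("wbc", *self.wbc_band),
            ("intermediate", *self.intermediate_band),
            ("large_single", *self.large_single_band),
            ("cluster_2plus", *self.cluster_2plus_band),
            ("cluster_3plus", self.cluster_3plus_min, float("inf")),
        ]
        for (_, _, hi), (_, lo2, _) in zip(out, out[1:]):
            if hi != lo2:
                raise ConfigError("bands must be contiguous")
        return out

    def __post_init__(self) -> None:
        self.bands()  # validates ordering/contiguity


@dataclass(frozen=True)
class ChannelGeometry:
    """Sorting-junction geometry; delta_um is the routing threshold."""

    width_um: float = 50.0
    height_um: float = 22.0
    delta_um: float = 8.3
    electrode_width_um: float = 13.0  # metadata

    def __post_init__(self) -> None:
        if not 0 < self.delta_um < self.width_um / 2:
            raise ConfigError("delta_um must lie in (0, width_um / 2)")


@dataclass(frozen=True)
class SortPulse:
    """DC pulse parameters and its modeled lateral displacement."""

    voltage_v: float = 40.0  # metadata
    duration_us: float = 100.0
    displacement_um: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_us <= 0:
            raise ConfigError("duration_us must be positive")
        if self.displacement_um < 0:
            raise ConfigError("displacement_um must be nonnegative")


@dataclass
class SortEvent:
    """Outcome of the trigger / pulse / routing sequence for one object."""

    object_id: int
    frame_index: int
    triggered: bool
    pulse: SortPulse | None
    displacement_um: float
    outlet: str  # "collection" | "discard"
    decision_latency_frames: int = 1  # logged only, never enforced


def classify(record: ObjectRecord, rules: BandRuleSet) -> str:
    """Label a record from its BF area band and nucleus consistency.

    No nucleus means debris regardless of size; cluster bands require at
    least 2 (or 3, above ``cluster_3plus_min``) nuclei, otherwise the
    object is a debris aggregate.
    """
    if rules.require_nucleus_consistency and record.nucleus_count == 0:
        return "debris"
    area = record.area_um2
    for name, lo, hi in rules.bands():
        if lo <= area < hi:
            band = name
            break
    else:
        raise InputError(f"area {area} um^2 below the classifiable floor")
    if not rules.require_nucleus_consistency:
        return band
    if band == "cluster_3plus":
        if record.nucleus_count >= 3:
            return "cluster_3plus"
        if record.nucleus_count == 2:
            return "cluster_2plus"  # nucleus evidence of a 2-cell cluster
        return "debris"
    if band == "cluster_2plus":
        return "cluster_2plus" if record.nucleus_count >= 2 else "debris"
    return band


def trigger_sort(record: ObjectRecord, area_threshold_um2: float = DEFAULT_TRIGGER_AREA_UM2) -> bool:
    """True iff the BF area strictly exceeds the target threshold."""
    return record.area_um2 > area_threshold_um2


def apply_pulse(triggered: bool, pulse: SortPulse) -> float:
    """Modeled lateral displacement: the pulse's constant if triggered, else 0."""
    return pulse.displacement_um if triggered else 0.0


def route_outlet(displacement_um: float, geometry: ChannelGeometry) -> str:
    """Collection iff displaced strictly more than delta from the channel center."""
    return "collection" if displacement_um > geometry.delta_um else "discard"


def run_sorting(
    records: list[ObjectRecord],
    rules: BandRuleSet | None = None,
    pulse: SortPulse | None = None,
    geometry: ChannelGeometry | None = None,
    area_threshold_um2: float = DEFAULT_TRIGGER_AREA_UM2,
    target_labels: tuple[str, ...] = DEFAULT_TARGET_LABELS,
) -> tuple[list[SortEvent], dict]:
    """Classify, trigger, pulse and route every record; log one event each.

    The summary reports totals plus yield and purity against ground
    truth when ``true_label`` is present (targets = ``target_labels``).
    """
    rules = rules or BandRuleSet()
    pulse = pulse or SortPulse()
    geometry = geometry or ChannelGeometry()
    events: list[SortEvent] = []
    for rec in records:
        if rec.label is None:
            rec.label = classify(rec, rules)
        triggered = trigger_sort(rec, area_threshold_um2)
        displacement = apply_pulse(triggered, pulse)
        outlet = route_outlet(displacement, geometry)
        events.append(
            SortEvent(
                object_id=rec.object_id,
                frame_index=rec.frame_index,
                triggered=triggered,
                pulse=pulse if triggered else None,
                displacement_um=displacement,
                outlet=outlet,
            )
        )

    n_collection = sum(1 for e in events if e.outlet == "collection")
    summary = {
        "n_total": len(records),
        "n_triggered": sum(1 for e in events if e.triggered),
        "n_collection": n_collection,
        "n_discard": len(records) - n_collection,
        "yield_pct": None,
        "purity_pct": None,
    }
    truth_known = [r for r in records if r.true_label is not None]
    if truth_known and len(truth_known) == len(records):
        by_id = {r.object_id: r for r in records}
        targets = [r for r in records if r.true_label in target_labels]
        collected = [e for e in events if e.outlet == "collection"]
        collected_targets = sum(
            1 for e in collected if by_id[e.object_id].true_label in target_labels
        )
        if targets:
            summary["yield_pct"] = 100.0 * collected_targets / len(targets)
        if collected:
            summary["purity_pct"] = 100.0 * collected_targets / len(collected)
    return events, summary
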