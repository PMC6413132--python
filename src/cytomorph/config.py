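"""Run configuration: defaults, validation, YAML round-trip, hashing.

Every default that mirrors a fixed system constant (300 um^2 trigger,
8.3 um routing threshold, 40 V / 100 us pulse, 16/256 FL floor, 20 um^2
reference nucleus, 20-um^2 area bins, 0.2 aspect-ratio bins) lives here
or in the dataclasses it aggregates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .distributions import DEFAULT_BIN_SPECS, BinSpec
from .errors import ConfigError
from .sorter import BandRuleSet, ChannelGeometry, SortPulse
from .synthgen import (
    OpticsModel,
    PopulationComponent,
    PopulationModel,
    StreamModel,
    default_population,
)

__all__ = ["Thresholds", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class Thresholds:
    """All scalar decision thresholds of the analysis pipeline."""

    bf_k: float = 3.0  # BF binarization: k x mean of the diff grid
    fl_floor: int = 16  # FL floor of 256 (4-bit recognition level)
    area_floor_um2: float = 10.0
    nucleus_floor_um2: float = 4.0
    trigger_area_um2: float = 300.0
    reference_nucleus_area_um2: float = 20.0
    min_seed_separation_um: float = 6.0
    match_tolerance_px: int = 2


@dataclass
class RunConfig:
    """Aggregated configuration for simulate / analyze / sort / dist runs."""

    seed: int = 1
    n_frames: int = 100
    optics: OpticsModel = field(default_factory=OpticsModel)
    stream: StreamModel = field(default_factory=StreamModel)
    population: dict = field(default_factory=lambda: {"kind": "positive", "day": 11})
    rules: BandRuleSet = field(default_factory=BandRuleSet)
    pulse: SortPulse = field(default_factory=SortPulse)
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    thresholds: Thresholds = field(default_factory=Thresholds)
    histograms: dict = field(
        default_factory=lambda: {k: dataclasses.asdict(v) for k, v in DEFAULT_BIN_SPECS.items()}
    )
    registration_offset: tuple[int, int] = (0, 0)
    target_labels: tuple[str, ...] = ("cluster",)

    def resolve_population(self) -> PopulationModel:
        spec = self.population
        if "components" in spec:
            comps = tuple(
                PopulationComponent(
                    **{
                        **c,
                        "area_support": tuple(c["area_support"]),
                        "cell_count_choices": tuple(c.get("cell_count_choices", (1,))),
                        "cell_count_probs": tuple(c.get("cell_count_probs", (1.0,))),
                    }
                )
                for c in spec["components"]
            )
            return PopulationModel(components=comps, day=spec.get("day", 11))
        return default_population(kind=spec.get("kind", "positive"), day=spec.get("day", 11))

    def bin_spec(self, variable: str) -> BinSpec:
        spec = self.histograms.get(variable)
        if spec is None:
            raise ConfigError(f"no bin spec configured for {variable!r}")
        return BinSpec(width=spec["width"], start=spec["start"])


_SECTION_TYPES = {
    "optics": OpticsModel,
    "stream": StreamModel,
    "rules": BandRuleSet,
    "pulse": SortPulse,
    "geometry": ChannelGeometry,
    "thresholds": Thresholds,
}
_TUPLE_FIELDS = {
    "rules": ("rbc_debris_band", "unclassified_small_band", "wbc_band",
              "intermediate_band", "large_single_band", "cluster_2plus_band"),
}


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    expected = {f.name for f in fields(cls)}
    unknown = set(data) - expected
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
    missing = expected - set(data)
    if missing:
        raise ConfigError(f"missing key(s) in {name!r}: {sorted(missing)}")
    clean = dict(data)
    for key in _TUPLE_FIELDS.get(name, ()):
        clean[key] = tuple(clean[key])
    try:
        return cls(**clean)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping.

    Sections that are present must be complete (every key named) and
    contain no unknown keys; absent sections take the defaults.
    """
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    known_top = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data[name])
    for name in ("seed", "n_frames", "population", "histograms"):
        if name in data:
            kwargs[name] = data[name]
    if "registration_offset" in data:
        off = data["registration_offset"]
        if len(off) != 2:
            raise ConfigError("registration_offset must have exactly two entries")
        kwargs["registration_offset"] = (int(off[0]), int(off[1]))
    if "target_labels" in data:
        kwargs["target_labels"] = tuple(data["target_labels"])
    cfg = RunConfig(**kwargs)
    cfg.resolve_population()  # fail fast on bad population specs
    for var, spec in cfg.histograms.items():
        if set(spec) != {"width", "start"}:
            raise ConfigError(f"histogram spec for {var!r} needs exactly width and start")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    out: dict = {
        "seed": cfg.seed,
        "n_frames": cfg.n_frames,
        "population": cfg.population,
        "histograms": cfg.histograms,
        "registration_offset": list(cfg.registration_offset),
        "target_labels": list(cfg.target_labels),
    }
    for name, _ in _SECTION_TYPES.items():
        section = dataclasses.asdict(getattr(cfg, name))
        for key, val in section.items():
            if isinstance(val, tuple):
                section[key] = list(val)
        out[name] = section
    return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
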