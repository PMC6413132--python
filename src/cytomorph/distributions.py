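"""Binned biomarker distributions and time-course analytics.

Histograms use the acquisition conventions throughout: half-open
[lo, hi) bins of fixed width (20 um^2 from 10 for area, 0.2 from 1 for
aspect ratio, 10 um for perimeter) with frequencies in percent of N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, InputError
from .sorter import BandRuleSet, ObjectRecord, classify

__all__ = [
    "BinSpec",
    "SizeHistogram",
    "BandFractions",
    "build_histogram",
    "detect_peaks",
    "band_fractions",
    "cellcount_nucleus_map",
    "average_cell_size",
    "compare_distributions",
    "DEFAULT_BIN_SPECS",
]


@dataclass(frozen=True)
class BinSpec:
    """Fixed-width half-open binning: edges at ``start + i * width``."""

    width: float
    start: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("bin width must be positive")


DEFAULT_BIN_SPECS = {
    "area_um2": BinSpec(width=20.0, start=10.0),
    "aspect_ratio": BinSpec(width=0.2, start=1.0),
    "perimeter_um": BinSpec(width=10.0, start=0.0),
}


@dataclass
class SizeHistogram:
    """Percent-normalized frequency distribution of one biomarker."""

    variable: str
    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    frequencies_pct: np.ndarray  # length n_bins, sums to 100 for N > 0
    n_total: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def proportions(self) -> np.ndarray:
        return self.frequencies_pct / 100.0


@dataclass
class BandFractions:
    """Per-class percentages plus the irregular-cell fraction.

    ``irregular_fraction_pct`` is 100 x clusters / WBC-band count; it is
    None (``undefined = True``) when no WBC-band object exists.
    """

    counts: dict[str, int]
    percents: dict[str, float]
    n_total: int
    irregular_fraction_pct: float | None
    undefined: bool = False


def build_histogram(values, variable: str, bin_spec: BinSpec | None = None) -> SizeHistogram:
    """Bin values into half-open fixed-width bins, frequencies in percent of N."""
    if bin_spec is None:
        try:
            bin_spec = DEFAULT_BIN_SPECS[variable]
        except KeyError:
            raise ConfigError(f"no default bin spec for variable {variable!r}") from None
    values = np.asarray(list(values), dtype=np.float64)
    if values.size == 0:
        edges = bin_spec.start + bin_spec.width * np.arange(2)
        return SizeHistogram(variable, edges, np.zeros(1), 0)
    idx = np.floor((values - bin_spec.start) / bin_spec.width).astype(np.int64)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = bin_spec.start + bin_spec.width * np.arange(lo, hi + 2)
    freq = 100.0 * counts / values.size
    return SizeHistogram(variable, edges, freq, int(values.size))


def detect_peaks(
    hist: SizeHistogram,
    smoothing_window: int = 3,
    min_prominence_pct: float = 0.2,
) -> list[tuple[float, float]]:
    """Local maxima of the smoothed frequency vector.

    Smoothing is a binomially weighted moving average (window 3:
    [1, 2, 1] / 4) with edge replication, so a flat histogram stays flat
    and yields no peaks while narrow modes keep their position.
    Returns ``(bin_center, raw_frequency_pct)`` pairs.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ConfigError("smoothing_window must be a positive odd integer")
    import math

    freq = hist.frequencies_pct.astype(np.float64)
    kernel = np.array([math.comb(smoothing_window - 1, i) for i in range(smoothing_window)], dtype=np.float64)
    kernel /= kernel.sum()
    pad = smoothing_window // 2
    padded = np.pad(freq, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    peaks, _ = find_peaks(smoothed, prominence=min_prominence_pct)
    centers = hist.bin_centers
    return [(float(centers[p]), float(hist.frequencies_pct[p])) for p in peaks]


def band_fractions(records: list[ObjectRecord], rules: BandRuleSet | None = None) -> BandFractions:
    """Classify records and report per-class percentages.

    The irregular fraction compares cluster-classified objects with the
    WBC-band count, the single-white-cell reference population.
    """
    rules = rules or BandRuleSet()
    counts: dict[str, int] = {}
    for rec in records:
        label = rec.label if rec.label is not None else classify(rec, rules)
        counts[label] = counts.get(label, 0) + 1
    n = len(records)
    percents = {k: 100.0 * v / n for k, v in counts.items()} if n else {}
    n_wbc = counts.get("wbc", 0)
    n_clusters = counts.get("cluster_2plus", 0) + counts.get("cluster_3plus", 0)
    if n_wbc == 0:
        return BandFractions(counts, percents, n, None, undefined=True)
    return BandFractions(counts, percents, n, 100.0 * n_clusters / n_wbc)


def cellcount_nucleus_map(records: list[ObjectRecord]) -> tuple[pd.DataFrame, dict]:
    """Joint (BF cell count, nucleus count) frequency table.

    The y = x diagonal is the one-nucleus-per-cell line; mass below it
    (nucleus count < cell count) flags debris-suspect objects.
    """
    pairs: dict[tuple[int, int], int] = {}
    for rec in records:
        key = (rec.cell_count_bf, rec.nucleus_count)
        pairs[key] = pairs.get(key, 0) + 1
    n = len(records)
    rows = [
        {
            "cell_count_bf": x,
            "nucleus_count": y,
            "count": c,
            "frequency_pct": 100.0 * c / n if n else 0.0,
        }
        for (x, y), c in sorted(pairs.items())
    ]
    table = pd.DataFrame(rows, columns=["cell_count_bf", "nucleus_count", "count", "frequency_pct"])
    diag = sum(c for (x, y), c in pairs.items() if x == y)
    below = sum(c for (x, y), c in pairs.items() if y < x)
    above = sum(c for (x, y), c in pairs.items() if y > x)
    masses = {
        "diagonal_pct": 100.0 * diag / n if n else 0.0,
        "below_diagonal_pct": 100.0 * below / n if n else 0.0,
        "above_diagonal_pct": 100.0 * above / n if n else 0.0,
    }
    return table, masses


def average_cell_size(record: ObjectRecord) -> float:
    """Object area divided by its nucleus count (debris: the area itself)."""
    return record.area_um2 / max(record.nucleus_count, 1)


def compare_distributions(hist_a: SizeHistogram, hist_b: SizeHistogram) -> dict:
    """Total-variation distance between two same-convention histograms.

    Histograms must share bin width and phase; supports are aligned on
    the union of their edges (missing bins count as zero).
    """
    wa = np.diff(hist_a.bin_edges)
    wb = np.diff(hist_b.bin_edges)
    if not (np.allclose(wa, wa[0]) and np.allclose(wb, wb[0]) and np.isclose(wa[0], wb[0])):
        raise InputError("histograms have mismatched bin widths")
    width = wa[0]
    phase_a = hist_a.bin_edges[0] / width
    phase_b = hist_b.bin_edges[0] / width
    if not np.isclose(phase_a - round(phase_a - phase_b) - phase_b, 0.0, atol=1e-9):
        raise InputError("histograms have mismatched bin phases")
    lo = min(hist_a.bin_edges[0], hist_b.bin_edges[0])
    hi = max(hist_a.bin_edges[-1], hist_b.bin_edges[-1])
    n_bins = int(round((hi - lo) / width))

    def aligned(h: SizeHistogram) -> np.ndarray:
        out = np.zeros(n_bins)
        off = int(round((h.bin_edges[0] - lo) / width))
        out[off : off + len(h.frequencies_pct)] = h.proportions
        return out

    p, q = aligned(hist_a), aligned(hist_b)
    edges = lo + width * np.arange(n_bins + 1)
    deltas = [
        {"bin_lo": float(edges[i]), "bin_hi": float(edges[i + 1]), "delta": float(p[i] - q[i])}
        for i in range(n_bins)
    ]
    return {"tv_distance": float(0.5 * np.abs(p - q).sum()), "per_bin_deltas": deltas}
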