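"""Condensate vs aggregate classification and partition arithmetic.

In-vitro phase-separation reactions of a disordered granule protein with RNA
produce either small, uniform RNA-dependent *condensates* or large, irregular
RNA-independent *aggregates*.  The two populations separate on a log10 total
object intensity axis, Log(I).  Reference reactions in which all objects are
known to be one class (no-RNA for aggregates; low-salt plus mRNA for
condensates) define Log(I) histograms whose intersection sets the class
boundary; objects at or below the boundary are condensates.

This module also carries the partition arithmetic converting a molecule
fraction *f* (fraction of a transcript's molecules inside granules) and a
volume fraction *v* (fraction of cell volume occupied by granules) into a
granule-over-cytoplasm concentration enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import BackgroundModel, DataQualityWarning

#: Default condensate/aggregate Log(I) boundary from the reference reactions.
DEFAULT_LOG_I_THRESHOLD = 4.6

#: Histogram bin width on the Log(I) axis, in log10 AU units.
LOG_I_BIN = 0.2

#: Histogram bin width on the radius axis, in micrometres.
RADIUS_BIN = 0.06


@dataclass(frozen=True)
class IntensityHistogram:
    """Normalized object-count histogram on a fixed-width grid anchored at 0.

    ``bin_edges`` has length ``len(frequencies) + 1``; every edge is an
    integer multiple of the bin width, so histograms from different runs
    share a grid and can be compared bin-by-bin.
    """

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        if edges.ndim != 1 or freq.ndim != 1 or edges.size != freq.size + 1:
            raise ValueError("bin_edges must have one more entry than frequencies")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequencies", freq)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class PhaseCall:
    """Per-object condensate/aggregate classes plus summary percentages."""

    classes: pd.Series  # "condensate" | "aggregate", indexed like the table
    threshold: float
    percent_condensate: float

    @property
    def percent_aggregate(self) -> float:
        return 100.0 - self.percent_condensate


def _histogram_from_values(values: np.ndarray, bin_width: float) -> IntensityHistogram:
    values = np.asarray(values, dtype=float)
    lo = int(np.floor(values.min() / bin_width))
    hi = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(lo, hi + 1, dtype=float) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return IntensityHistogram(edges, counts / counts.sum(), int(values.size))


def log_intensity_histogram(
    table: pd.DataFrame, bin_width: float = LOG_I_BIN
) -> IntensityHistogram:
    """Bin Log(I) of each object and normalize to the object count.

    Zero-intensity objects have no Log(I) and are dropped with a warning; a
    table with no positive-intensity objects is an error.
    """
    if len(table) == 0:
        raise ValueError("cannot histogram an empty object table")
    logs = table["log_intensity"].to_numpy(dtype=float)
    good = np.isfinite(logs)
    if (~good).any():
        warnings.warn(
            f"dropped {int((~good).sum())} zero-intensity object(s) from Log(I) histogram",
            DataQualityWarning,
            stacklevel=2,
        )
    logs = logs[good]
    if logs.size == 0:
        raise ValueError("all objects have zero intensity; no Log(I) histogram")
    return _histogram_from_values(logs, bin_width)


def _aligned(
    h1: IntensityHistogram, h2: IntensityHistogram
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-express two anchored, equal-width histograms on their union grid."""
    w = h1.bin_width
    if abs(h2.bin_width - w) > 1e-12:
        raise ValueError("histograms must share a bin width")
    i1 = int(round(h1.bin_edges[0] / w))
    i2 = int(round(h2.bin_edges[0] / w))
    lo = min(i1, i2)
    hi = max(i1 + h1.frequencies.size, i2 + h2.frequencies.size)
    f1 = np.zeros(hi - lo)
    f2 = np.zeros(hi - lo)
    f1[i1 - lo : i1 - lo + h1.frequencies.size] = h1.frequencies
    f2[i2 - lo : i2 - lo + h2.frequencies.size] = h2.frequencies
    centers = (np.arange(lo, hi) + 0.5) * w
    return centers, f1, f2


def intersection_threshold(
    h_cond: IntensityHistogram, h_agg: IntensityHistogram
) -> float:
    """Log(I) boundary at the intersection of two reference histograms.

    The condensate histogram must peak below the aggregate histogram.  The
    threshold is the centre of the bin, between the two modes, where the sign
    of ``h_cond - h_agg`` changes and the pointwise minimum of the two
    histograms is smallest; exact ties break toward the lower bin.  If the
    supports do not overlap, the midpoint between them is returned with a
    warning.
    """
    centers, fc, fa = _aligned(h_cond, h_agg)
    mode_c = int(np.argmax(fc))
    mode_a = int(np.argmax(fa))
    if mode_c >= mode_a:
        raise ValueError("condensate histogram mode must lie below aggregate mode")

    sup_c = np.flatnonzero(fc)
    sup_a = np.flatnonzero(fa)
    if sup_c[-1] < sup_a[0]:  # disjoint supports
        warnings.warn(
            "reference histograms do not overlap; threshold set to the "
            "midpoint between their supports",
            DataQualityWarning,
            stacklevel=2,
        )
        return float(0.5 * (centers[sup_c[-1]] + centers[sup_a[0]]))

    diff = fc - fa
    candidates = []
    for i in range(mode_c + 1, mode_a + 1):
        if diff[i - 1] > 0 and diff[i] <= 0:
            candidates.append(i)
    if not candidates:
        # overlap exists but no crossing strictly between modes: use the bin
        # with minimal pointwise overlap between the modes
        candidates = list(range(mode_c + 1, mode_a + 1))
    overlap = np.minimum(fc, fa)
    best = min(candidates, key=lambda i: (overlap[i], i))
    return float(centers[best])


def classify_objects(
    table: pd.DataFrame, threshold: float = DEFAULT_LOG_I_THRESHOLD
) -> PhaseCall:
    """Call each object condensate (Log(I) <= threshold) or aggregate.

    The boundary value itself is a condensate.  Objects whose Log(I) sits
    exactly on the boundary are counted, and a warning is raised when the
    boundary convention moves the condensate percentage by more than half a
    point (the alternative convention would call them aggregates).
    """
    logs = table["log_intensity"].to_numpy(dtype=float) if len(table) else np.array([])
    is_cond = logs <= threshold
    n = logs.size
    pct = 100.0 * is_cond.sum() / n if n else float("nan")
    on_boundary = int((logs == threshold).sum())
    if n and 100.0 * on_boundary / n > 0.5:
        warnings.warn(
            f"{on_boundary} object(s) sit exactly on the Log(I) boundary; the "
            "boundary-class convention shifts percent condensate by "
            f"{100.0 * on_boundary / n:.2f} points",
            DataQualityWarning,
            stacklevel=2,
        )
    classes = pd.Series(
        np.where(is_cond, "condensate", "aggregate"), index=table.index, name="phase"
    )
    return PhaseCall(classes=classes, threshold=float(threshold), percent_condensate=float(pct))


def condition_state(call: PhaseCall, table: pd.DataFrame) -> str:
    """Predominant state of a reaction: soluble | condensate | aggregate.

    No detected objects means the protein stayed soluble.  Otherwise the class
    holding the larger total integrated intensity wins; ties go to aggregate
    (the larger-object class by construction).
    """
    if len(table) == 0:
        return "soluble"
    name = table.attrs.get("intensity_channel")
    col = f"corrected_{name}" if name else next(
        c for c in table.columns if c.startswith("corrected_")
    )
    intens = table[col].to_numpy(dtype=float)
    cond_total = intens[(call.classes == "condensate").to_numpy()].sum()
    agg_total = intens[(call.classes == "aggregate").to_numpy()].sum()
    return "condensate" if cond_total > agg_total else "aggregate"


def rna_fraction_in_objects(
    rna_channel: np.ndarray,
    labels: np.ndarray,
    bg: BackgroundModel | float,
) -> float:
    """Percent of total image RNA signal found inside protein objects.

    The background-corrected RNA intensity summed over labelled pixels is
    divided by the background-corrected total over the whole imaged area.
    """
    rna = np.asarray(rna_channel, dtype=float)
    bg_mean = bg.mean if isinstance(bg, BackgroundModel) else float(bg)
    corrected = rna - bg_mean
    total = float(corrected.sum())
    if total <= 0:
        warnings.warn("total RNA signal <= 0; fraction undefined", DataQualityWarning, stacklevel=2)
        return float("nan")
    inside = float(corrected[labels > 0].sum())
    return 100.0 * inside / total


@dataclass(frozen=True)
class RadiusHistogram:
    """Normalized radius histogram plus the sub-400 nm object fraction."""

    histogram: IntensityHistogram
    fraction_below_400nm: float


def radii_histogram(table: pd.DataFrame, bin_width: float = RADIUS_BIN) -> RadiusHistogram:
    """Bin object radii (µm) and report the fraction with radius < 0.4 µm."""
    if len(table) == 0:
        raise ValueError("cannot histogram radii of an empty object table")
    radii = table["radius"].to_numpy(dtype=float)
    hist = _histogram_from_values(radii, bin_width)
    return RadiusHistogram(hist, float((radii < 0.4).mean()))


def concentration_enrichment(f: float, v: float, *, cytoplasm_ratio: bool = True) -> float:
    """Fold concentration of a transcript in granules over the cytoplasm.

    With molecule fraction ``f`` in granules occupying volume fraction ``v``,
    the granule concentration is proportional to ``f/v`` and the cytoplasm
    concentration to ``(1-f)/(1-v)``; their ratio is
    ``(f/v) * ((1-v)/(1-f))``.  ``cytoplasm_ratio=False`` returns the plain
    ``f/v`` enrichment over the whole-cell average instead.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError("f must lie in [0, 1)")
    if not (0.0 < v < 1.0):
        raise ValueError("v must lie in (0, 1)")
    if not cytoplasm_ratio:
        return f / v
    return (f / v) * ((1.0 - v) / (1.0 - f))
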