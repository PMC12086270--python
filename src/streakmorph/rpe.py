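"""RPE mosaic morphometry from 1-D nucleus traces.

The retinal pigment epithelium (RPE) is modelled as a mosaic of regular
hexagonal cells.  Nucleus centres are annotated along a dorsoventral
segment (default 250 μm); the consecutive internuclear distance D is the
horizontal cell extension, identified with twice the apothem (h = D/2) of
the hexagon.  With side a = D/√3 the cell base area is

    A = 3·h·a = (√3 / 2) · D².

Two artifacts corrupt raw distances and are filtered with a median rule
computed once on the unfiltered distances:

* binucleate cells — two nuclei inside one cell produce a spuriously short
  gap; gaps below half the median are classified ``binucleate`` and the
  two nuclei are replaced by their midpoint (the cell centre);
* missing nuclei — an undetected nucleus fuses two gaps; gaps above twice
  the median are classified ``dropout`` and excluded from distance
  statistics (no imputation).

Boundary gaps exactly at half or twice the median are kept as normal
(strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

SQRT3 = math.sqrt(3.0)

GapLabel = Literal["normal", "binucleate", "dropout"]


@dataclass
class RPETrace:
    """Ordered RPE nucleus positions along a 1-D retinal segment."""

    animal_id: str
    region: str
    positions: np.ndarray  # μm, strictly increasing
    segment_length: float = 250.0  # μm, half-open segment [0, L)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.positions.size:
            if self.positions.min() < 0 or self.positions.max() >= self.segment_length:
                raise ValueError("positions must lie in [0, segment_length)")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n_nuclei(self) -> int:
        return int(self.positions.size)


@dataclass
class GapClassification:
    distances: np.ndarray  # raw internuclear distances, μm
    median_distance: float  # μm, computed on the raw distances
    lower_threshold: float  # μm, median / 2
    upper_threshold: float  # μm, 2 × median
    labels: np.ndarray  # GapLabel per gap


@dataclass
class CorrectionResult:
    positions: np.ndarray  # corrected nucleus positions, μm
    corrected_distances: np.ndarray  # μm, dropout gaps excluded
    n_raw_nuclei: int
    n_corrected_nuclei: int
    n_merges: int
    n_chain_conflicts: int  # consecutive binucleate gaps resolved greedily
    binucleate_fraction: float  # flagged gaps / raw nuclei (reporting convention)
    binucleate_cell_prob: float  # merges / corrected cells (estimates the cell-level rate)
    dropout_fraction: float  # dropout gaps / raw gaps


@dataclass
class MosaicResult:
    animal_id: str
    region: str
    raw_distances: np.ndarray = field(repr=False)
    median_distance: float = np.nan
    lower_threshold: float = np.nan
    upper_threshold: float = np.nan
    classifications: np.ndarray = field(default=None, repr=False)
    corrected_distances: np.ndarray = field(default=None, repr=False)
    mean_corrected_distance: float = np.nan
    binucleate_fraction: float = np.nan
    binucleate_cell_prob: float = np.nan
    dropout_fraction: float = np.nan
    cell_area: float = np.nan  # μm², from the mean corrected distance
    cell_area_per_gap: float = np.nan  # μm², mean of per-distance areas
    hexagon_side: float = np.nan  # μm, a = D/√3
    hexagon_height: float = np.nan  # μm, apothem h = D/2


def internuclear_distances(trace: RPETrace | Sequence[float]) -> np.ndarray:
    """Consecutive differences of nucleus positions (μm)."""
    positions = trace.positions if isinstance(trace, RPETrace) else np.asarray(trace, dtype=float)
    if positions.size < 2:
        raise ValueError("at least two nucleus positions are required")
    d = np.diff(positions)
    if np.any(d <= 0):
        raise ValueError("positions must be strictly increasing")
    return d


def classify_gaps(
    distances: Sequence[float], median_distance: float | None = None
) -> GapClassification:
    """Median-threshold artifact classification of internuclear distances.

    The median is taken over the raw (unfiltered) distances unless an
    external value is supplied — e.g. the pooled median of a whole region
    when several segments are analysed against common thresholds.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot classify an empty distance list")
    med = float(np.median(d)) if median_distance is None else float(median_distance)
    lower, upper = med / 2.0, 2.0 * med
    labels = np.full(d.shape, "normal", dtype=object)
    labels[d < lower] = "binucleate"
    labels[d > upper] = "dropout"
    return GapClassification(d, med, lower, upper, labels)


def correct_binucleates(
    trace: RPETrace,
    classification: GapClassification,
    mode: Literal["midpoint", "remove"] = "midpoint",
) -> CorrectionResult:
    """Apply the artifact corrections to a classified trace.

    ``midpoint`` (default): each binucleate gap's two nuclei are merged at
    their midpoint — the presumed cell centre — and distances are
    recomputed from the merged positions.  ``remove``: binucleate gaps are
    excluded from the distance list without merging (the alternative of
    dropping binucleate cells from area statistics altogether).

    Consecutive binucleate gaps (three short-spaced nuclei in a chain) are
    resolved greedily left-to-right: the first pair is merged, the
    following gap is left in place and counted as a chain conflict.
    Dropout gaps are excluded from the corrected distances but their
    flanking nuclei are retained.  Every raw nucleus is either retained or
    merged, never silently dropped.
    """
    positions = trace.positions
    labels = np.asarray(classification.labels, dtype=object)
    n = positions.size
    if labels.size != n - 1:
        raise ValueError("classification does not align with the trace gaps")

    n_flagged = int(np.sum(labels == "binucleate"))
    n_dropout = int(np.sum(labels == "dropout"))

    new_positions: list[float] = []
    last_raw_index: list[int] = []  # raw index of the last nucleus in each cluster
    n_merges = 0
    n_chain_conflicts = 0
    i = 0
    while i < n:
        if mode == "midpoint" and i < n - 1 and labels[i] == "binucleate":
            if i + 1 < n - 1 and labels[i + 1] == "binucleate":
                n_chain_conflicts += 1
            new_positions.append(0.5 * (positions[i] + positions[i + 1]))
            last_raw_index.append(i + 1)
            n_merges += 1
            i += 2
        else:
            new_positions.append(float(positions[i]))
            last_raw_index.append(i)
            i += 1

    corrected_positions = np.asarray(new_positions)
    # Each corrected gap spans exactly one raw gap: the one between the
    # last nucleus of the left cluster and the first of the right cluster.
    corrected: list[float] = []
    for k in range(len(corrected_positions) - 1):
        raw_gap = last_raw_index[k]
        if labels[raw_gap] == "dropout":
            continue
        if mode == "remove" and labels[raw_gap] == "binucleate":
            continue
        corrected.append(corrected_positions[k + 1] - corrected_positions[k])

    n_corrected = len(corrected_positions)
    return CorrectionResult(
        positions=corrected_positions,
        corrected_distances=np.asarray(corrected),
        n_raw_nuclei=n,
        n_corrected_nuclei=n_corrected,
        n_merges=n_merges,
        n_chain_conflicts=n_chain_conflicts,
        binucleate_fraction=n_flagged / n if n else np.nan,
        binucleate_cell_prob=n_merges / n_corrected if n_corrected else np.nan,
        dropout_fraction=n_dropout / (n - 1) if n > 1 else np.nan,
    )


def hexagon_area(distance: float) -> float:
    """Base area (μm²) of the regular hexagonal cell with horizontal
    extension ``distance`` = 2 × apothem: A = (√3/2)·D²."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return (SQRT3 / 2.0) * distance * distance


def hexagon_geometry(distance: float) -> tuple[float, float, float]:
    """(area A, side a = D/√3, apothem h = D/2) of the hexagon model.

    The identities h = (√3/2)·a and A = 3·h·a hold by construction.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    a = distance / SQRT3
    h = distance / 2.0
    return 3.0 * h * a, a, h


def relative_increase(value: float, reference: float) -> float:
    """Percent increase of ``value`` over ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return (value / reference - 1.0) * 100.0


def phagosomes_per_cell(phagosome_count: float, rpe_cell_count: float) -> float:
    """Phagocytosed outer-segment tips per RPE cell in one window."""
    if rpe_cell_count <= 0:
        raise ValueError("rpe_cell_count must be positive")
    return phagosome_count / rpe_cell_count


def analyze_trace(
    trace: RPETrace,
    mode: Literal["midpoint", "remove"] = "midpoint",
    median_distance: float | None = None,
) -> MosaicResult:
    """Full mosaic analysis of a single trace: distances → median-threshold
    classification → binucleate/dropout correction → hexagon-model areas."""
    raw = internuclear_distances(trace)
    cls = classify_gaps(raw, median_distance=median_distance)
    corr = correct_binucleates(trace, cls, mode=mode)
    mean_d = float(np.mean(corr.corrected_distances)) if corr.corrected_distances.size else np.nan
    area, side, height = hexagon_geometry(mean_d) if np.isfinite(mean_d) else (np.nan, np.nan, np.nan)
    per_gap = (
        float(np.mean([(SQRT3 / 2.0) * d * d for d in corr.corrected_distances]))
        if corr.corrected_distances.size
        else np.nan
    )
    return MosaicResult(
        animal_id=trace.animal_id,
        region=trace.region,
        raw_distances=raw,
        median_distance=cls.median_distance,
        lower_threshold=cls.lower_threshold,
        upper_threshold=cls.upper_threshold,
        classifications=cls.labels,
        corrected_distances=corr.corrected_distances,
        mean_corrected_distance=mean_d,
        binucleate_fraction=corr.binucleate_fraction,
        binucleate_cell_prob=corr.binucleate_cell_prob,
        dropout_fraction=corr.dropout_fraction,
        cell_area=area,
        cell_area_per_gap=per_gap,
        hexagon_side=side,
        hexagon_height=height,
    )


def analyze_region(
    traces: Iterable[RPETrace],
    region: str | None = None,
    mode: Literal["midpoint", "remove"] = "midpoint",
) -> MosaicResult:
    """Pooled mosaic analysis of several traces from one region.

    The artifact thresholds come from the median of all raw distances of
    the region pooled together (the thresholds the study applied to each
    region's full data set); corrections are then applied per trace.
    """
    traces = [t for t in traces if region is None or t.region == region]
    if not traces:
        raise ValueError("no traces to analyse")
    raw_all = np.concatenate([internuclear_distances(t) for t in traces])
    pooled_median = float(np.median(raw_all))

    corrected_all: list[np.ndarray] = []
    n_raw_nuclei = n_flagged = n_dropout = n_merges = n_corrected = 0
    labels_all: list[np.ndarray] = []
    for t in traces:
        raw = internuclear_distances(t)
        cls = classify_gaps(raw, median_distance=pooled_median)
        corr = correct_binucleates(t, cls, mode=mode)
        corrected_all.append(corr.corrected_distances)
        labels_all.append(cls.labels)
        n_raw_nuclei += t.n_nuclei
        n_flagged += int(np.sum(cls.labels == "binucleate"))
        n_dropout += int(np.sum(cls.labels == "dropout"))
        n_merges += corr.n_merges
        n_corrected += corr.n_corrected_nuclei

    corrected = np.concatenate(corrected_all) if corrected_all else np.empty(0)
    mean_d = float(np.mean(corrected)) if corrected.size else np.nan
    area, side, height = hexagon_geometry(mean_d) if np.isfinite(mean_d) else (np.nan, np.nan, np.nan)
    n_gaps = raw_all.size
    return MosaicResult(
        animal_id="pooled",
        region=region if region is not None else traces[0].region,
        raw_distances=raw_all,
        median_distance=pooled_median,
        lower_threshold=pooled_median / 2.0,
        upper_threshold=2.0 * pooled_median,
        classifications=np.concatenate(labels_all),
        corrected_distances=corrected,
        mean_corrected_distance=mean_d,
        binucleate_fraction=n_flagged / n_raw_nuclei if n_raw_nuclei else np.nan,
        binucleate_cell_prob=n_merges / n_corrected if n_corrected else np.nan,
        dropout_fraction=n_dropout / n_gaps if n_gaps else np.nan,
        cell_area=area,
        cell_area_per_gap=float(np.mean((SQRT3 / 2.0) * corrected**2)) if corrected.size else np.nan,
        hexagon_side=side,
        hexagon_height=height,
    )
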