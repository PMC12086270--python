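"""Synthetic annotation tables with known ground truth.

The generator emits the same *annotation-level* records that manual
quantification of stained retinal cross-sections produces — never pixels:

* per-window section records (cone counts, ONL rows, nucleus diameters,
  outer-segment lengths, RPE heights, phagosome and RPE cell counts);
* 1-D RPE nucleus traces with jittered spacing, planted binucleate cells
  and nucleus dropouts, with per-nucleus truth labels;
* a log-normal protein-intensity matrix with planted log2 fold-changes
  and missing values.

Distributional choices (the measured study reports means ± SD only):
counts are Poisson, continuous measurements are Gaussian truncated at
zero, and internuclear gaps are Gamma with the stated mean and CV — a
positive, mildly right-skewed family consistent with a raw-distance
median below the mean.  Region defaults are anchored to the measured
visual-streak (VS), near-periphery (NP) and far-periphery (FP) values of
the Mongolian gerbil retina.  All randomness flows through explicit
seeds; identical seeds give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import ProteinMatrix
from .rpe import RPETrace

#: Marker proteins of interest (rod/cone outer segments, phagocytosis
#: machinery, visual cycle); planted up-regulated in the VS group by default.
DEFAULT_MARKER_PANEL = ("RHO", "OPN1MW", "MERTK", "GAS6", "PTK2", "ABCA4", "RDH8")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generating parameters for one eccentricity region."""

    region_name: str
    cone_rate: float  # expected cones per 1,200 μm² window
    onl_rows: float  # mean ONL row count
    nucleus_diameter: float  # μm, mean ONL nucleus diameter
    os_length_mean: float  # μm
    os_length_sd: float  # μm
    rpe_spacing_mean: float  # μm, internuclear spacing
    rpe_spacing_cv: float  # unitless coefficient of variation
    binucleate_prob: float  # probability a cell is binucleate
    dropout_prob: float  # probability a nucleus is missing from the trace
    binucleate_offset: float  # μm, within-cell nucleus separation
    phagosome_rate: float  # expected phagosomes per RPE cell
    rpe_height_mean: float  # μm
    rpe_height_sd: float = 2.0  # μm
    onl_rows_sd: float = 0.4
    nucleus_diameter_sd: float = 0.1  # μm
    n_sections: int = 4  # sections per animal
    n_animals: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cone_rate",
            "onl_rows",
            "nucleus_diameter",
            "os_length_mean",
            "rpe_spacing_mean",
            "phagosome_rate",
            "rpe_height_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("binucleate_prob", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.rpe_spacing_cv:
            raise ValueError("rpe_spacing_cv must be non-negative")
        if not 0.0 < self.binucleate_offset < self.rpe_spacing_mean / 2.0:
            raise ValueError(
                "binucleate_offset must be positive and below half the mean "
                "spacing so planted binucleates fall under the half-median filter"
            )
        if self.n_sections < 1 or self.n_animals < 1:
            raise ValueError("n_sections and n_animals must be >= 1")


def default_region_truth() -> dict[str, TruthParams]:
    """Study-condition defaults, anchored to the measured region values.

    Cone rates are the measured densities scaled to the 1,200 μm² window
    (e.g. VS: 50,660/mm² → 60.792 per window); ONL rows are chosen so
    that rows × 1200/diameter² reproduces the measured rod densities at a
    5 μm nucleus diameter.  RPE spacing, binucleate and dropout rates
    follow the measured VS/periphery mosaic values; near-periphery RPE
    values are interpolated (the mosaic was measured in VS and periphery
    only).  Phagosome rates implement the measured ~39.3% VS elevation
    over the periphery.
    """
    return {
        "VS": TruthParams(
            region_name="VS",
            cone_rate=60.792,
            onl_rows=8.6254,
            nucleus_diameter=5.0,
            os_length_mean=22.47,
            os_length_sd=2.71,
            rpe_spacing_mean=19.16,
            rpe_spacing_cv=0.15,
            binucleate_prob=0.14,
            dropout_prob=0.04,
            binucleate_offset=3.0,
            phagosome_rate=2.786,
            rpe_height_mean=12.08,
            rpe_height_sd=2.5,
        ),
        "NP": TruthParams(
            region_name="NP",
            cone_rate=45.2916,
            onl_rows=8.4848,
            nucleus_diameter=5.0,
            os_length_mean=14.3,
            os_length_sd=2.53,
            rpe_spacing_mean=21.0,
            rpe_spacing_cv=0.15,
            binucleate_prob=0.12,
            dropout_prob=0.05,
            binucleate_offset=3.0,
            phagosome_rate=2.4,
            rpe_height_mean=9.5,
            rpe_height_sd=2.2,
        ),
        "FP": TruthParams(
            region_name="FP",
            cone_rate=34.1712,
            onl_rows=7.8237,
            nucleus_diameter=5.0,
            os_length_mean=11.59,
            os_length_sd=1.2,
            rpe_spacing_mean=22.59,
            rpe_spacing_cv=0.15,
            binucleate_prob=0.10,
            dropout_prob=0.05,
            binucleate_offset=3.0,
            phagosome_rate=2.0,
            rpe_height_mean=7.0,
            rpe_height_sd=2.0,
        ),
    }


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian truncated at zero (measurements are physical lengths/counts)."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_sections(
    truth: TruthParams | Mapping[str, TruthParams],
    seed: int | None = None,
    width: float = 100.0,
    thickness: float = 12.0,
) -> pd.DataFrame:
    """Generate per-window section records for one or several regions.

    Cone and phagosome counts are Poisson; continuous measurements are
    truncated Gaussian.  The RPE cell count per window is Poisson with
    mean width/spacing (at least one cell).  One animal's rows share the
    animal id across regions, mimicking the repeated-measures design.
    """
    regions = {truth.region_name: truth} if isinstance(truth, TruthParams) else dict(truth)
    first = next(iter(regions.values()))
    rng = np.random.default_rng(first.seed if seed is None else seed)
    rows = []
    for region, p in regions.items():
        for a in range(p.n_animals):
            n = p.n_sections
            cones = rng.poisson(p.cone_rate, size=n)
            onl = _truncated_normal(rng, p.onl_rows, p.onl_rows_sd, n)
            diam = _truncated_normal(rng, p.nucleus_diameter, p.nucleus_diameter_sd, n)
            osl = _truncated_normal(rng, p.os_length_mean, p.os_length_sd, n)
            height = _truncated_normal(rng, p.rpe_height_mean, p.rpe_height_sd, n)
            cells = np.maximum(1, rng.poisson(width / p.rpe_spacing_mean, size=n))
            phago = rng.poisson(p.phagosome_rate * cells)
            for s in range(n):
                rows.append(
                    {
                        "animal_id": f"A{a + 1}",
                        "region": region,
                        "section_id": f"S{s + 1}",
                        "width_um": width,
                        "thickness_um": thickness,
                        "cone_count": int(cones[s]),
                        "onl_rows": float(onl[s]),
                        "nucleus_diameter_um": float(diam[s]),
                        "os_length_um": float(osl[s]),
                        "rpe_height_um": float(height[s]),
                        "phagosome_count": int(phago[s]),
                        "rpe_cell_count": int(cells[s]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticTrace:
    """An RPE nucleus trace plus its generating truth."""

    trace: RPETrace
    nuclei: pd.DataFrame = field(repr=False)  # position_um, cell_index, is_binucleate_cell
    n_cells: int
    n_binucleate_cells: int
    n_dropped_nuclei: int
    empty: bool = False

    @property
    def planted_binucleate_fraction(self) -> float:
        """Cell-level truth: binucleate cells / cells."""
        return self.n_binucleate_cells / self.n_cells if self.n_cells else np.nan


def generate_rpe_trace(
    params: TruthParams,
    segment_length: float = 250.0,
    seed: int | None = None,
    animal_id: str = "A1",
) -> SyntheticTrace:
    """Generate one 1-D RPE nucleus trace with planted artifacts.

    Cell centres are laid down by cumulative Gamma gaps with the stated
    mean and CV; each cell is independently binucleate (two nuclei at
    centre ± offset/2), and each nucleus is independently dropped from the
    observed trace with the dropout probability.  Per-nucleus truth
    labels are returned alongside the observed trace.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    if params.rpe_spacing_mean >= segment_length:
        raise ValueError("rpe_spacing_mean must be smaller than the segment length")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    m, cv = params.rpe_spacing_mean, params.rpe_spacing_cv
    margin = params.binucleate_offset / 2.0
    centers: list[float] = []
    pos = 0.0
    # draw gaps in blocks for speed on long segments
    expected = max(int(segment_length / m * 1.3) + 16, 16)
    while True:
        if cv == 0:
            gaps = np.full(expected, m)
        else:
            shape = 1.0 / (cv * cv)
            gaps = rng.gamma(shape, m / shape, size=expected)
        for g in gaps:
            pos += g
            if pos >= segment_length - margin:
                break
            centers.append(pos)
        if pos >= segment_length - margin:
            break

    n_cells = len(centers)
    binucleate = rng.random(n_cells) < params.binucleate_prob
    records = []
    for i, c in enumerate(centers):
        if binucleate[i]:
            records.append((c - margin, i, True))
            records.append((c + margin, i, True))
        else:
            records.append((c, i, False))
    nuclei = pd.DataFrame(records, columns=["position_um", "cell_index", "is_binucleate_cell"])
    dropped = rng.random(len(nuclei)) < params.dropout_prob
    nuclei["observed"] = ~dropped
    observed = nuclei.loc[nuclei["observed"]].sort_values("position_um")
    positions = observed["position_um"].to_numpy()

    empty = positions.size == 0
    trace = RPETrace(
        animal_id=animal_id,
        region=params.region_name,
        positions=positions,
        segment_length=segment_length,
    )
    return SyntheticTrace(
        trace=trace,
        nuclei=nuclei,
        n_cells=n_cells,
        n_binucleate_cells=int(binucleate.sum()),
        n_dropped_nuclei=int(dropped.sum()),
        empty=empty,
    )


def generate_protein_matrix(
    n_proteins: int,
    groups: Mapping[str, int],
    planted_effects: Sequence[tuple[int, float]] = (),
    missing_prob: float = 0.0,
    seed: int | None = None,
    baseline_mean: float = 20.0,
    baseline_sd: float = 2.0,
    within_sd: float = 0.3,
    protein_ids: Sequence[str] | None = None,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Log-normal protein matrix with planted fold-changes.

    ``groups`` maps group label → replicate count (insertion order fixes
    the group order; planted log2 fold-changes shift the *first* group).
    Intensities are 2**Normal(μ_p, within_sd) with protein baselines
    μ_p ~ Normal(baseline_mean, baseline_sd).  Missingness is independent
    per cell.  Returns the raw-scale matrix and the planted-effect truth.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 replicates")
    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError("missing_prob must lie in [0, 1]")
    for idx, _ in planted_effects:
        if not 0 <= idx < n_proteins:
            raise ValueError(f"planted protein index {idx} out of range")

    rng = np.random.default_rng(seed)
    labels = list(groups)
    sample_ids = [f"{g}_{r + 1}" for g in labels for r in range(groups[g])]
    group_of_sample = [g for g in labels for _ in range(groups[g])]
    n_samples = len(sample_ids)

    baseline = rng.normal(baseline_mean, baseline_sd, size=(n_proteins, 1))
    log2_values = baseline + rng.normal(0.0, within_sd, size=(n_proteins, n_samples))
    first_cols = [j for j, g in enumerate(group_of_sample) if g == labels[0]]
    for idx, lfc in planted_effects:
        log2_values[idx, first_cols] += lfc

    values = np.power(2.0, log2_values)
    if missing_prob > 0:
        values[rng.random(values.shape) < missing_prob] = np.nan

    if protein_ids is None:
        protein_ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    else:
        protein_ids = list(protein_ids)
        if len(protein_ids) != n_proteins:
            raise ValueError("protein_ids length must equal n_proteins")

    truth = pd.DataFrame(
        [
            {"protein_index": idx, "protein_id": protein_ids[idx], "log2_fc": lfc}
            for idx, lfc in planted_effects
        ],
        columns=["protein_index", "protein_id", "log2_fc"],
    )
    matrix = ProteinMatrix(protein_ids, sample_ids, group_of_sample, values, "raw")
    return matrix, truth


@dataclass
class SyntheticBundle:
    """Everything a full pipeline run needs, with the generating truth."""

    sections: pd.DataFrame
    traces: list[SyntheticTrace]
    protein_matrix: ProteinMatrix
    protein_truth: pd.DataFrame
    truth: dict[str, TruthParams]
    seed: int


def generate_bundle(
    seed: int = 0,
    region_truth: Mapping[str, TruthParams] | None = None,
    n_traces_per_animal: int = 4,
    n_proteins: int = 2000,
    n_planted: int = 50,
    planted_log2_fc: float = 2.0,
    protein_replicates: int = 3,
    missing_prob: float = 0.05,
    protein_within_sd: float = 0.3,
) -> SyntheticBundle:
    """One full synthetic study at the default (measured-value-anchored)
    conditions: sections and RPE traces for every region and animal, and a
    VS-vs-periphery protein matrix with planted effects.

    The first ``len(DEFAULT_MARKER_PANEL)`` planted proteins carry the
    marker names (rhodopsin, M-opsin, MERTK, Gas6, FAK, ABCA4, RDH8).
    """
    truth = dict(region_truth) if region_truth is not None else default_region_truth()
    rng = np.random.default_rng(seed)

    sections = generate_sections(truth, seed=int(rng.integers(2**31)))

    traces: list[SyntheticTrace] = []
    for region, p in truth.items():
        for a in range(p.n_animals):
            for _ in range(n_traces_per_animal):
                traces.append(
                    generate_rpe_trace(
                        p, seed=int(rng.integers(2**31)), animal_id=f"A{a + 1}"
                    )
                )

    n_named = min(len(DEFAULT_MARKER_PANEL), n_planted)
    protein_ids = list(DEFAULT_MARKER_PANEL[:n_named]) + [
        f"P{i + 1:05d}" for i in range(n_proteins - n_named)
    ]
    planted = [(i, planted_log2_fc) for i in range(n_planted)]
    matrix, protein_truth = generate_protein_matrix(
        n_proteins,
        {"VS": protein_replicates, "periphery": protein_replicates},
        planted_effects=planted,
        missing_prob=missing_prob,
        seed=int(rng.integers(2**31)),
        within_sd=protein_within_sd,
        protein_ids=protein_ids,
    )
    return SyntheticBundle(sections, traces, matrix, protein_truth, truth, seed)


def traces_to_frame(traces: Sequence[SyntheticTrace | RPETrace]) -> pd.DataFrame:
    """Long-format trace table: one observed nucleus per row."""
    rows = []
    for k, t in enumerate(traces):
        tr = t.trace if isinstance(t, SyntheticTrace) else t
        for p in tr.positions:
            rows.append(
                {
                    "animal_id": tr.animal_id,
                    "region": tr.region,
                    "trace_id": f"T{k + 1}",
                    "segment_length_um": tr.segment_length,
                    "position_um": float(p),
                }
            )
    return pd.DataFrame(rows)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write sections.tsv, traces.tsv, proteins.tsv, groups.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sections": outdir / "sections.tsv",
        "traces": outdir / "traces.tsv",
        "proteins": outdir / "proteins.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.sections.to_csv(paths["sections"], sep="\t", index=False)
    traces_to_frame(bundle.traces).to_csv(paths["traces"], sep="\t", index=False)
    bundle.protein_matrix.to_frame().to_csv(paths["proteins"], sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": bundle.protein_matrix.sample_ids,
            "group": bundle.protein_matrix.groups,
        }
    ).to_csv(paths["groups"], sep="\t", index=False)
    truth_payload = {
        "seed": bundle.seed,
        "regions": {r: asdict(p) for r, p in bundle.truth.items()},
        "planted_proteins": bundle.protein_truth.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2))
    return paths
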