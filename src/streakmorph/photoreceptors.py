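"""Photoreceptor density stereology for retinal cross-sections.

Cone and rod densities are estimated from manual counts made in small
quantification windows (default 100 μm dorsoventral extent × 12 μm section
thickness, i.e. 1,200 μm² of retinal surface) and extrapolated to 1 mm².
Cones are counted directly through the z-stack.  Rods are estimated
stereologically from the number of photoreceptor rows in the outer nuclear
layer (ONL) and the mean ONL nucleus diameter: the rows span the window
width, and the nucleus diameter sets how many cells fit both along the
width and through the section thickness.

The rod-to-cone ratio (RCR) — rod density over cone density — is the
topographic marker of interest: it is low in high-acuity regions (visual
streak, macula) and high in the unspecialized periphery.  Cone density is
the denominator because it never reaches zero, while rod density does (in
the fovea).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Region labels in eccentricity order: visual streak, near periphery, far periphery.
REGIONS: tuple[str, ...] = ("VS", "NP", "FP")

#: μm² per mm².
UM2_PER_MM2 = 1.0e6


@dataclass
class SectionRecord:
    """One quantification window of a retinal cross-section.

    Counts may be fractional: per-animal averages of several sections are
    legitimate inputs and no rounding is performed internally.
    """

    animal_id: str
    region: str
    cone_count: float
    onl_rows: float
    nucleus_diameter: float  # μm
    os_length: float = np.nan  # μm, mean of three single measurements
    rpe_height: float = np.nan  # μm
    phagosome_count: float = np.nan
    rpe_cell_count: float = np.nan
    width: float = 100.0  # μm, dorsoventral extent
    thickness: float = 12.0  # μm, z dimension (section thickness)
    section_id: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.thickness <= 0:
            raise ValueError("window width and thickness must be positive")
        if self.nucleus_diameter <= 0:
            raise ValueError("nucleus_diameter must be positive")
        for name in ("cone_count", "onl_rows"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def window_area_um2(self) -> float:
        return self.width * self.thickness


@dataclass
class DensityResult:
    """Per-region density summary across animals.

    ``rcr_values`` holds one RCR per animal (ratio of that animal's mean
    densities); ``rcr_of_means`` is the alternative estimator formed from
    the region-level mean densities.  Both reproduce the same display
    values on the study's data; they differ in general.
    """

    region: str
    n_animals: int
    cone_density_mean: float
    cone_density_sd: float
    rod_density_mean: float
    rod_density_sd: float
    rcr_values: np.ndarray = field(repr=False)
    rcr_mean: float = np.nan
    rcr_sd: float = np.nan
    rcr_median: float = np.nan
    rcr_q25: float = np.nan
    rcr_q75: float = np.nan
    rcr_of_means: float = np.nan


def cone_density(section: SectionRecord) -> float:
    """Cone density in cones/mm² from a single quantification window."""
    area = section.window_area_um2
    if area <= 0:
        raise ValueError("window area must be positive")
    return section.cone_count * (UM2_PER_MM2 / area)


def rod_density(section: SectionRecord) -> float:
    """Rod density in rods/mm² via ONL row stereology.

    Rods per window = onl_rows × (width / nucleus_diameter) ×
    (thickness / nucleus_diameter): each ONL row contributes
    width/diameter nuclei along the section and thickness/diameter nuclei
    through its depth.  Fractional values are retained.
    """
    if section.nucleus_diameter <= 0:
        raise ValueError("nucleus_diameter must be positive")
    d = section.nucleus_diameter
    rods_per_window = section.onl_rows * (section.width / d) * (section.thickness / d)
    return rods_per_window * (UM2_PER_MM2 / section.window_area_um2)


def rod_to_cone_ratio(rod_dens: float, cone_dens: float) -> float:
    """Rod-to-cone ratio.  Cone density is the only valid denominator
    (rod density vanishes in foveate retinas)."""
    if cone_dens <= 0:
        raise ValueError(
            "cone density must be positive: rod density is not a valid "
            "denominator and a zero cone density leaves the RCR undefined"
        )
    return rod_dens / cone_dens


# metric name -> callable on a SectionRecord
_DERIVED_METRICS = {
    "cone_density": cone_density,
    "rod_density": rod_density,
    "rcr": lambda s: rod_to_cone_ratio(rod_density(s), cone_density(s)),
    "phagosomes_per_cell": lambda s: s.phagosome_count / s.rpe_cell_count,
}
_RAW_METRICS = (
    "cone_count",
    "onl_rows",
    "nucleus_diameter",
    "os_length",
    "rpe_height",
    "phagosome_count",
    "rpe_cell_count",
)


def known_metrics() -> tuple[str, ...]:
    return tuple(_DERIVED_METRICS) + _RAW_METRICS


def sections_to_frame(sections: Iterable[SectionRecord]) -> pd.DataFrame:
    rows = []
    for s in sections:
        rows.append(
            {
                "animal_id": s.animal_id,
                "region": s.region,
                "section_id": s.section_id,
                "width_um": s.width,
                "thickness_um": s.thickness,
                "cone_count": s.cone_count,
                "onl_rows": s.onl_rows,
                "nucleus_diameter_um": s.nucleus_diameter,
                "os_length_um": s.os_length,
                "rpe_height_um": s.rpe_height,
                "phagosome_count": s.phagosome_count,
                "rpe_cell_count": s.rpe_cell_count,
            }
        )
    return pd.DataFrame(rows)


def per_animal_means(
    sections: Sequence[SectionRecord], metric: str
) -> pd.DataFrame:
    """First aggregation level: section values averaged within each animal.

    Returns a frame with columns ``animal_id``, ``region``, ``value``.
    """
    if metric in _DERIVED_METRICS:
        fn = _DERIVED_METRICS[metric]
        values = [fn(s) for s in sections]
    elif metric in _RAW_METRICS:
        values = [getattr(s, metric) for s in sections]
    else:
        raise KeyError(
            f"unknown metric {metric!r}; known metrics: {sorted(known_metrics())}"
        )
    df = pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in sections],
            "region": [s.region for s in sections],
            "value": values,
        }
    )
    counts = df.groupby(["region", "animal_id"], sort=True)["value"].count()
    if (counts == 0).any():
        raise ValueError("every animal must contribute at least one section")
    return (
        df.groupby(["region", "animal_id"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def region_summary(sections: Sequence[SectionRecord], metric: str) -> pd.DataFrame:
    """Two-level summary: sections → per-animal mean → across-animal stats.

    The SD is across animals (the biological replication unit); with a
    single animal it is undefined and reported as NaN with
    ``sd_defined = False``.  Quantiles are computed on the per-animal
    values (25/75% box limits, 5/95% whiskers, as in the study's plots).
    """
    per_animal = per_animal_means(sections, metric)
    out = []
    for region, grp in per_animal.groupby("region", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        n = len(v)
        out.append(
            {
                "region": region,
                "metric": metric,
                "n_animals": n,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if n > 1 else np.nan,
                "sd_defined": n > 1,
                "median": float(np.median(v)),
                "q05": float(np.quantile(v, 0.05)),
                "q25": float(np.quantile(v, 0.25)),
                "q75": float(np.quantile(v, 0.75)),
                "q95": float(np.quantile(v, 0.95)),
            }
        )
    return pd.DataFrame(out)


def density_table(sections: Sequence[SectionRecord]) -> list[DensityResult]:
    """Per-region cone/rod densities and RCR (both estimators)."""
    cones = per_animal_means(sections, "cone_density")
    rods = per_animal_means(sections, "rod_density")
    merged = cones.merge(rods, on=["region", "animal_id"], suffixes=("_cone", "_rod"))
    results = []
    for region, grp in merged.groupby("region", sort=True):
        c = grp["value_cone"].to_numpy(dtype=float)
        r = grp["value_rod"].to_numpy(dtype=float)
        rcr = np.array([rod_to_cone_ratio(ri, ci) for ri, ci in zip(r, c)])
        n = len(c)
        results.append(
            DensityResult(
                region=region,
                n_animals=n,
                cone_density_mean=float(np.mean(c)),
                cone_density_sd=float(np.std(c, ddof=1)) if n > 1 else np.nan,
                rod_density_mean=float(np.mean(r)),
                rod_density_sd=float(np.std(r, ddof=1)) if n > 1 else np.nan,
                rcr_values=rcr,
                rcr_mean=float(np.mean(rcr)),
                rcr_sd=float(np.std(rcr, ddof=1)) if n > 1 else np.nan,
                rcr_median=float(np.median(rcr)),
                rcr_q25=float(np.quantile(rcr, 0.25)),
                rcr_q75=float(np.quantile(rcr, 0.75)),
                rcr_of_means=rod_to_cone_ratio(float(np.mean(r)), float(np.mean(c))),
            )
        )
    return results


def format_rcr(rcr: float, region: str) -> str:
    """Display convention: one decimal place in the visual streak, nearest
    integer elsewhere."""
    return f"{rcr:.1f}" if region == "VS" else f"{rcr:.0f}"
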