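"""Repeated-measures group statistics on per-animal summaries.

Each animal contributes one value per eccentricity region (a complete
repeated-measures design).  Two regions are compared with a two-tailed
paired Student t-test; three regions with a repeated-measures one-way
ANOVA whose degrees of freedom are always Greenhouse–Geisser adjusted
(unconditional application is conservative and reproducible), followed by
Bonferroni-corrected pairwise paired t-tests.  Shapiro–Wilk normality
p-values are reported alongside as advisories; they never gate the
pipeline.  Significance stars follow the usual thresholds with strict
inequalities: * p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats


@dataclass
class PairedDesign:
    """Complete repeated-measures layout: one value per animal per group."""

    animal_ids: list[str]
    group_labels: list[str]
    values: np.ndarray  # shape (n_animals, n_groups)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_a, n_g = self.values.shape
        if len(self.animal_ids) != n_a or len(self.group_labels) != n_g:
            raise ValueError("labels do not match the value matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("repeated-measures design requires complete cases")
        if n_a < 3:
            raise ValueError("at least three animals are required for testing")

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, value: str = "value",
        animal: str = "animal_id", group: str = "region",
        group_order: Sequence[str] | None = None,
    ) -> "PairedDesign":
        wide = df.pivot(index=animal, columns=group, values=value)
        if group_order is not None:
            wide = wide[[g for g in group_order if g in wide.columns]]
        if wide.isna().any().any():
            raise ValueError("incomplete design: some animals lack values in some groups")
        return cls(
            animal_ids=[str(a) for a in wide.index],
            group_labels=[str(g) for g in wide.columns],
            values=wide.to_numpy(),
        )


@dataclass
class StatReport:
    test_name: str
    statistic: float
    p_value: float
    stars: str
    adjusted_p: dict[str, float] = field(default_factory=dict)
    normality_p: float | None = None
    df: tuple[float, ...] = ()
    epsilon: float | None = None  # Greenhouse–Geisser epsilon (RM-ANOVA)


def star_labels(p: float) -> str:
    """Significance stars; strict thresholds, most extreme wins."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


def shapiro_screen(values: Sequence[float]) -> float:
    """Shapiro–Wilk normality p-value (advisory only)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(stats.shapiro(v).pvalue)


def paired_t(design: PairedDesign) -> StatReport:
    """Two-tailed paired Student t-test on a two-group design."""
    if len(design.group_labels) != 2:
        raise ValueError("paired_t requires exactly two groups")
    a, b = design.values[:, 0], design.values[:, 1]
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        raise ValueError(
            "paired differences have zero variance: t statistic undefined "
            f"(constant effect {diffs[0]:g})"
        )
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    try:
        norm_p = shapiro_screen(diffs)
    except ValueError:
        norm_p = np.nan
    return StatReport(
        test_name="paired t",
        statistic=float(res.statistic),
        p_value=p,
        stars=star_labels(p),
        normality_p=norm_p,
        df=(float(len(diffs) - 1),),
    )


def _rm_anova_gg(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """RM-ANOVA F with Greenhouse–Geisser correction via pingouin.

    Returns (F, p_gg, epsilon, df1_gg, df2_gg).  Degenerate designs with
    zero between-condition variation return F = 0, p = 1.
    """
    n_a, n_g = values.shape
    grand = values.mean()
    col_means = values.mean(axis=0)
    ss_treat = n_a * np.sum((col_means - grand) ** 2)
    if np.isclose(ss_treat, 0.0):
        return 0.0, 1.0, 1.0, float(n_g - 1), float((n_a - 1) * (n_g - 1))

    long = pd.DataFrame(
        {
            "animal": np.repeat(np.arange(n_a), n_g),
            "group": np.tile(np.arange(n_g), n_a),
            "y": values.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="y", within="group", subject="animal",
        correction=True, detailed=True,
    )
    row = aov.loc[aov["Source"] == "group"].iloc[0]
    F = float(row["F"])
    eps = float(row["eps"]) if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan)) else 1.0
    df1, df2 = float(n_g - 1), float((n_a - 1) * (n_g - 1))
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
    return F, p_gg, eps, eps * df1, eps * df2


def rm_anova_bonferroni(design: PairedDesign) -> StatReport:
    """Repeated-measures one-way ANOVA (Greenhouse–Geisser corrected)
    with Bonferroni-adjusted pairwise paired t-tests."""
    n_groups = len(design.group_labels)
    if n_groups < 2:
        raise ValueError("at least two groups are required")
    F, p_gg, eps, df1, df2 = _rm_anova_gg(design.values)

    pairs = list(combinations(range(n_groups), 2))
    adjusted: dict[str, float] = {}
    for i, j in pairs:
        a, b = design.values[:, i], design.values[:, j]
        if np.std(a - b, ddof=1) == 0:
            praw = 1.0 if np.allclose(a, b) else np.nan
        else:
            praw = float(stats.ttest_rel(a, b).pvalue)
        key = f"{design.group_labels[i]}-{design.group_labels[j]}"
        adjusted[key] = min(1.0, len(pairs) * praw) if np.isfinite(praw) else np.nan

    try:
        norm_p = shapiro_screen(design.values.ravel())
    except ValueError:
        norm_p = np.nan
    return StatReport(
        test_name="RM one-way ANOVA (GG) + Bonferroni",
        statistic=F,
        p_value=p_gg,
        stars=star_labels(p_gg),
        adjusted_p=adjusted,
        normality_p=norm_p,
        df=(df1, df2),
        epsilon=eps,
    )


def bonferroni(p_values: Sequence[float], n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p × m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if n_comparisons is None else n_comparisons
    return np.minimum(1.0, p * m)


def stats_table(
    per_animal: pd.DataFrame,
    metric: str,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the appropriate battery on a per-animal long table
    (animal_id, region, value) and return tidy rows for stats.tsv."""
    design = PairedDesign.from_long(per_animal, group_order=group_order)
    rows = []
    if len(design.group_labels) == 2:
        rep = paired_t(design)
        rows.append(
            {
                "metric": metric,
                "comparison": "-".join(design.group_labels),
                "test": rep.test_name,
                "statistic": rep.statistic,
                "p_value": rep.p_value,
                "adjusted_p": rep.p_value,
                "stars": rep.stars,
                "normality_p": rep.normality_p,
            }
        )
    else:
        rep = rm_anova_bonferroni(design)
        rows.append(
            {
                "metric": metric,
                "comparison": "|".join(design.group_labels),
                "test": rep.test_name,
                "statistic": rep.statistic,
                "p_value": rep.p_value,
                "adjusted_p": rep.p_value,
                "stars": rep.stars,
                "normality_p": rep.normality_p,
            }
        )
        n_pairs = len(rep.adjusted_p)
        for comparison, adj in rep.adjusted_p.items():
            i, j = (design.group_labels.index(g) for g in comparison.split("-"))
            a, b = design.values[:, i], design.values[:, j]
            raw = (
                float(stats.ttest_rel(a, b).pvalue)
                if np.std(a - b, ddof=1) > 0
                else np.nan
            )
            rows.append(
                {
                    "metric": metric,
                    "comparison": comparison,
                    "test": "paired t (Bonferroni)",
                    "statistic": np.nan,
                    "p_value": raw,
                    "adjusted_p": adj,
                    "stars": star_labels(adj) if np.isfinite(adj) else "",
                    "normality_p": np.nan,
                }
            )
    return pd.DataFrame(rows)
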