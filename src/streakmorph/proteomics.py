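"""Differential protein abundance with permutation-based FDR control.

The pipeline mirrors the standard label-free quantitative-proteomics
workflow on a protein-group × sample intensity matrix:

1. keep only proteins quantified in **all** replicates of at least one
   biological group (group-completeness filter; missing values are never
   imputed);
2. log2-transform the raw intensities so that fold-changes become
   differences;
3. per-protein two-sample t-test between the two groups, with
   significance controlled by a permutation-based false discovery rate at
   q < 0.05 built from whole-column label permutations.

The permutation statistic is the SAM-style moderated t

    d_i = (mean₁ − mean₂) / (se_i + s0),

where se_i is the per-protein standard error of the mean difference and
s0 is a small positive fudge factor that damps the heavy small-sample
tail of the plain t statistic (proteins with accidentally tiny variance).
By default s0 is the median of the per-protein standard errors; s0 = 0
recovers the plain t.  For each candidate threshold (every observed
|d|), the estimated FDR is the average number of permuted-null
exceedances — with add-one smoothing, which matters when few distinct
label assignments exist — divided by the observed count; q-values are
made monotone in |d| by a running minimum from the least significant end.

Group sizes of two or fewer replicates cannot support permutation
inference; a warning is emitted below three replicates per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProteinMatrix:
    """Protein-group quantification matrix (proteins × samples).

    ``values`` holds raw intensities (strictly positive where present) or
    log2 intensities depending on ``scale``; NaN marks a missing value.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    groups: list[str]  # biological group per sample
    values: np.ndarray  # shape (n_proteins, n_samples)
    scale: Literal["raw", "log2"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_p, n_s = self.values.shape
        if len(self.protein_ids) != n_p:
            raise ValueError("protein_ids length does not match matrix rows")
        if len(self.sample_ids) != n_s or len(self.groups) != n_s:
            raise ValueError("sample_ids/groups length does not match matrix columns")
        if len(set(self.protein_ids)) != n_p:
            raise ValueError("duplicate protein ids")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def columns_of(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups, dtype=object) == group)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "protein_id", self.protein_ids)
        return df

    @classmethod
    def from_tables(
        cls,
        matrix: pd.DataFrame,
        groups: pd.DataFrame,
        scale: Literal["raw", "log2"] = "raw",
    ) -> "ProteinMatrix":
        """Build from a matrix table (first column = protein id) and a
        sample → group mapping table with columns sample_id, group."""
        protein_ids = matrix.iloc[:, 0].astype(str).tolist()
        sample_ids = [str(c) for c in matrix.columns[1:]]
        mapping = dict(zip(groups["sample_id"].astype(str), groups["group"].astype(str)))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        values = matrix.iloc[:, 1:].to_numpy(dtype=float)
        return cls(protein_ids, sample_ids, [mapping[s] for s in sample_ids], values, scale)


class FilterResult(NamedTuple):
    matrix: ProteinMatrix
    n_retained: int
    n_removed: int


class PermutationInfo(NamedTuple):
    n_permutations: int
    exhaustive: bool
    s0: float
    seed: int | None


def group_completeness_filter(matrix: ProteinMatrix) -> FilterResult:
    """Retain proteins quantified in all replicates of at least one group."""
    keep = np.zeros(matrix.values.shape[0], dtype=bool)
    for g in matrix.group_labels:
        cols = matrix.columns_of(g)
        keep |= ~np.isnan(matrix.values[:, cols]).any(axis=1)
    n_retained = int(keep.sum())
    n_removed = int((~keep).sum())
    if n_retained == 0:
        warnings.warn("group-completeness filter removed every protein")
    filtered = replace(
        matrix,
        protein_ids=[p for p, k in zip(matrix.protein_ids, keep) if k],
        values=matrix.values[keep],
    )
    return FilterResult(filtered, n_retained, n_removed)


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Elementwise log2 of raw intensities; missing values stay missing."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    bad = np.argwhere(matrix.values <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive intensity at protein {matrix.protein_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}: {matrix.values[r, c]}"
        )
    return replace(matrix, values=np.log2(matrix.values), scale="log2")


def _two_sample_stats(
    X: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    s0: float,
    welch: bool,
    min_obs: int,
):
    """Vectorised available-case two-sample statistics.

    Returns (d, t, df, diff, valid): the moderated statistic d (with s0),
    the plain t, its degrees of freedom, the mean difference and a
    validity mask (>= min_obs complete observations per group and a
    defined standard error).
    """
    A, B = X[:, idx1], X[:, idx2]
    n1 = (~np.isnan(A)).sum(axis=1)
    n2 = (~np.isnan(B)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        m1, m2 = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        v1, v2 = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
    valid = (n1 >= max(min_obs, 2)) & (n2 >= max(min_obs, 2))
    n1s, n2s = np.maximum(n1, 2), np.maximum(n2, 2)
    if welch:
        se2 = v1 / n1s + v2 / n2s
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1s) ** 2 / (n1s - 1) + (v2 / n2s) ** 2 / (n2s - 1)
            )
        se = np.sqrt(se2)
    else:
        df = (n1s + n2s - 2).astype(float)
        sp2 = ((n1s - 1) * v1 + (n2s - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1s + 1.0 / n2s))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        d = diff / (se + s0)
    # identical values in both groups: no evidence, not an undefined ratio
    no_signal = (se == 0) & (diff == 0)
    t[no_signal] = 0.0
    d[no_signal & (s0 == 0)] = 0.0
    t[~valid] = np.nan
    d[~valid] = np.nan
    return d, t, df, diff, valid


def _label_assignments(
    n_samples: int,
    idx1: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], bool]:
    """Whole-column group-label permutations.

    If the number of distinct informative assignments is at most the
    requested count, enumerate them exhaustively: all ways to choose the
    first group, excluding the observed labelling and — for equal group
    sizes — de-duplicated against complement swaps (a labelling and its
    complement give identical |statistics| and would otherwise place a
    hard floor of 1/B on every q-value).  Otherwise draw random
    permutations of the columns.
    """
    n1 = idx1.size
    n2 = n_samples - n1
    observed = frozenset(int(i) for i in idx1)
    all_idx = np.arange(n_samples)

    n_distinct = comb(n_samples, n1)
    n_effective = n_distinct // 2 if n1 == n2 else n_distinct
    n_effective -= 1  # identity labelling

    if n_effective <= n_permutations:
        assignments = []
        seen: set[frozenset] = set()
        for c in combinations(range(n_samples), n1):
            key = frozenset(c)
            comp = frozenset(set(range(n_samples)) - set(c))
            if key == observed or (n1 == n2 and comp == observed):
                continue
            if n1 == n2:
                pair = frozenset([key, comp])
                if pair in seen:
                    continue
                seen.add(pair)
            a = np.fromiter(c, dtype=int)
            b = np.setdiff1d(all_idx, a)
            assignments.append((a, b))
        return assignments, True

    assignments = []
    while len(assignments) < n_permutations:
        perm = rng.permutation(n_samples)
        a = np.sort(perm[:n1])
        if frozenset(int(i) for i in a) == observed:
            continue
        b = np.setdiff1d(all_idx, a)
        assignments.append((a, b))
    return assignments, False


def permutation_fdr_ttest(
    matrix: ProteinMatrix,
    n_permutations: int = 250,
    fdr_threshold: float = 0.05,
    seed: int | None = None,
    group1: str | None = None,
    group2: str | None = None,
    s0: float | Literal["auto"] = "auto",
    test: Literal["student", "welch"] = "student",
    estimator: Literal["mean", "median"] = "mean",
    min_obs: int = 2,
) -> tuple[pd.DataFrame, PermutationInfo]:
    """Per-protein two-sample t-tests with permutation-based FDR control.

    Returns a result table (protein_id, log2_fc, t_stat, d_stat, p_raw,
    q_value, significant, n1, n2) and the permutation bookkeeping.
    ``log2_fc`` is mean(group1) − mean(group2).
    """
    if matrix.scale != "log2":
        raise ValueError("matrix must be log2-transformed first")
    labels = matrix.group_labels
    if group1 is None or group2 is None:
        if len(labels) != 2:
            raise ValueError("specify group1/group2 for matrices with more than two groups")
        group1, group2 = labels[0], labels[1]
    idx1, idx2 = matrix.columns_of(group1), matrix.columns_of(group2)
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("at least two replicates per group are required")
    if min(idx1.size, idx2.size) < 3:
        warnings.warn(
            "fewer than three replicates in a group: permutation inference "
            "is unreliable at this sample size"
        )

    X = matrix.values[:, np.concatenate([idx1, idx2])]
    j1 = np.arange(idx1.size)
    j2 = np.arange(idx1.size, idx1.size + idx2.size)
    welch = test == "welch"

    if s0 == "auto":
        _, _, _, _, valid0 = _two_sample_stats(X, j1, j2, 0.0, welch, min_obs)
        with np.errstate(divide="ignore", invalid="ignore"):
            d0, t0, _, diff0, _ = _two_sample_stats(X, j1, j2, 0.0, welch, min_obs)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_obs = np.abs(diff0[valid0] / t0[valid0])
        se_obs = se_obs[np.isfinite(se_obs)]
        s0_value = float(np.median(se_obs)) if se_obs.size else 0.0
    else:
        s0_value = float(s0)

    d_obs, t_obs, df_obs, diff_obs, valid = _two_sample_stats(
        X, j1, j2, s0_value, welch, min_obs
    )
    p_raw = np.full(d_obs.shape, np.nan)
    with np.errstate(invalid="ignore"):
        p_raw[valid] = 2.0 * stats.t.sf(np.abs(t_obs[valid]), df_obs[valid])

    rng = np.random.default_rng(seed)
    assignments, exhaustive = _label_assignments(
        X.shape[1], j1, n_permutations, rng
    )
    B = len(assignments)

    abs_d = np.abs(d_obs[valid])
    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    obs_count = np.arange(1, thresholds.size + 1, dtype=float)

    per_perm_ratio: list[np.ndarray] = []
    total_null = np.zeros(thresholds.size)
    for a, b in assignments:
        d_null, _, _, _, valid_n = _two_sample_stats(X, a, b, s0_value, welch, min_obs)
        dn = np.sort(np.abs(d_null[valid_n]))
        counts = dn.size - np.searchsorted(dn, thresholds, side="left")
        total_null += counts
        if estimator == "median":
            per_perm_ratio.append(counts / obs_count)

    if estimator == "median":
        fdr = np.median(np.vstack(per_perm_ratio), axis=0) if per_perm_ratio else np.ones_like(thresholds)
    else:
        fdr = ((1.0 + total_null) / max(B, 1)) / obs_count
    # monotone in evidence: running minimum from the least significant end
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q_valid = np.empty_like(q_sorted)
    q_valid[order] = q_sorted
    q = np.full(d_obs.shape, np.nan)
    q[valid] = q_valid

    results = pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "log2_fc": diff_obs,
            "t_stat": t_obs,
            "d_stat": d_obs,
            "p_raw": p_raw,
            "q_value": q,
            "significant": (q < fdr_threshold) & valid,
            "n1": (~np.isnan(X[:, j1])).sum(axis=1),
            "n2": (~np.isnan(X[:, j2])).sum(axis=1),
        }
    )
    info = PermutationInfo(B, exhaustive, s0_value, seed)
    return results, info


def marker_panel_report(
    results: pd.DataFrame, panel: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Subset the differential-abundance results to a named protein panel.

    Returns the panel rows with a direction flag (up/down/unchanged with
    respect to group1) and the list of panel ids absent from the results.
    """
    panel = list(panel)
    present = results[results["protein_id"].isin(panel)].copy()
    missing = [p for p in panel if p not in set(results["protein_id"])]
    direction = np.where(
        present["log2_fc"] > 0, "up", np.where(present["log2_fc"] < 0, "down", "unchanged")
    )
    present["direction"] = direction
    order = {p: i for i, p in enumerate(panel)}
    present = present.sort_values("protein_id", key=lambda s: s.map(order))
    return present.reset_index(drop=True), missing
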