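"""Completeness filtering, log2 transform and permutation-FDR behaviour."""

import numpy as np
import pandas as pd
import pytest

from streakmorph.proteomics import (
    ProteinMatrix,
    group_completeness_filter,
    log2_transform,
    marker_panel_report,
    permutation_fdr_ttest,
)
from streakmorph.synthetic import generate_protein_matrix


def matrix(values, groups=("a", "a", "a", "b", "b", "b"), scale="raw", ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ProteinMatrix(ids, samples, list(groups), values, scale)


class TestCompletenessFilter:
    def test_complete_in_one_group_retained(self):
        m = matrix([[1, 2, 3, np.nan, 5, np.nan]])
        res = group_completeness_filter(m)
        assert res.n_retained == 1 and res.n_removed == 0

    def test_missing_in_every_group_removed(self):
        m = matrix(
            [
                [1, np.nan, 3, 4, np.nan, 6],
                [1, 2, 3, 4, 5, 6],
            ]
        )
        res = group_completeness_filter(m)
        assert res.n_retained == 1
        assert res.matrix.protein_ids == ["P1"]

    def test_fully_complete_matrix_is_identity(self):
        m = matrix(np.arange(12.0).reshape(2, 6) + 1)
        res = group_completeness_filter(m)
        assert res.matrix.protein_ids == m.protein_ids
        np.testing.assert_array_equal(res.matrix.values, m.values)

    def test_idempotent(self):
        m = matrix(
            [
                [1, 2, 3, np.nan, 5, 6],
                [np.nan, 2, 3, np.nan, 5, 6],
            ]
        )
        once = group_completeness_filter(m).matrix
        twice = group_completeness_filter(once).matrix
        assert once.protein_ids == twice.protein_ids
        np.testing.assert_array_equal(once.values, twice.values, strict=True)

    def test_empty_result_warns(self):
        m = matrix([[np.nan, 2, 3, np.nan, 5, 6]])
        with pytest.warns(UserWarning, match="every protein"):
            group_completeness_filter(m)


class TestLog2:
    def test_values(self):
        m = log2_transform(matrix([[1024, 1, 2, 4, 8, 16]]))
        np.testing.assert_allclose(m.values, [[10, 0, 1, 2, 3, 4]])
        assert m.scale == "log2"

    def test_double_transform_guard(self):
        m = log2_transform(matrix([[1, 2, 3, 4, 5, 6]]))
        with pytest.raises(ValueError, match="already"):
            log2_transform(m)

    def test_nonpositive_cell_named(self):
        with pytest.raises(ValueError, match=r"P1.*s2"):
            log2_transform(matrix([[1, 2, 3, 4, 5, 6], [1, 2, 0, 4, 5, 6]]))

    def test_missing_stays_missing(self):
        m = log2_transform(matrix([[2, np.nan, 8, 4, 2, 2]]))
        assert np.isnan(m.values[0, 1])


class TestPermutationFDR:
    @staticmethod
    def logged(values, **kwargs):
        return matrix(np.asarray(values, float), scale="log2", **kwargs)

    def test_identical_values_never_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(20, 1, size=(200, 6))
        v[0] = 7.0  # identical in both groups
        res, _ = permutation_fdr_ttest(self.logged(v), seed=1)
        row = res.iloc[0]
        assert row["t_stat"] == 0.0 and not row["significant"]

    def test_determinism(self):
        rng = np.random.default_rng(1)
        v = rng.normal(20, 1, size=(300, 10))
        groups = ["a"] * 5 + ["b"] * 5
        r1, _ = permutation_fdr_ttest(self.logged(v, groups=groups), seed=42)
        r2, _ = permutation_fdr_ttest(self.logged(v, groups=groups), seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        v = rng.normal(20, 1, size=(300, 6))
        v[:20, :3] += 1.5
        m = self.logged(v)
        r1, _ = permutation_fdr_ttest(m, seed=3, group1="a", group2="b")
        r2, _ = permutation_fdr_ttest(m, seed=3, group1="b", group2="a")
        np.testing.assert_allclose(r2["log2_fc"], -r1["log2_fc"])
        np.testing.assert_allclose(r2["t_stat"], -r1["t_stat"])
        np.testing.assert_allclose(r2["q_value"], r1["q_value"])

    def test_exhaustive_enumeration_at_tiny_n(self):
        rng = np.random.default_rng(3)
        v = rng.normal(20, 1, size=(100, 6))
        _, info = permutation_fdr_ttest(self.logged(v), n_permutations=250, seed=4)
        # C(6,3)/2 - 1 = 9 informative assignments at n = 3 vs 3
        assert info.exhaustive and info.n_permutations == 9

    def test_random_sampling_at_larger_n(self):
        rng = np.random.default_rng(4)
        v = rng.normal(20, 1, size=(50, 14))
        groups = ["a"] * 7 + ["b"] * 7
        _, info = permutation_fdr_ttest(
            self.logged(v, groups=groups), n_permutations=250, seed=5
        )
        assert not info.exhaustive and info.n_permutations == 250

    def test_q_monotone_in_evidence(self):
        rng = np.random.default_rng(5)
        v = rng.normal(20, 1, size=(500, 6))
        v[:30, :3] += 2.0
        res, _ = permutation_fdr_ttest(self.logged(v), seed=6)
        res = res.dropna(subset=["q_value"]).sort_values(
            "d_stat", key=np.abs, ascending=False
        )
        assert (np.diff(res["q_value"]) >= -1e-12).all()

    def test_requires_log2_scale(self):
        with pytest.raises(ValueError, match="log2"):
            permutation_fdr_ttest(matrix(np.ones((5, 6))))

    def test_small_group_warns(self):
        rng = np.random.default_rng(6)
        v = rng.normal(20, 1, size=(50, 4))
        with pytest.warns(UserWarning, match="replicates"):
            permutation_fdr_ttest(self.logged(v, groups=("a", "a", "b", "b")), seed=7)

    def test_available_case_minimum_guard(self):
        v = np.full((3, 6), 20.0)
        v += np.arange(6) * 0.1
        v[0, [0, 1]] = np.nan  # one usable replicate in group a
        res, _ = permutation_fdr_ttest(self.logged(v), seed=8)
        assert np.isnan(res.loc[0, "q_value"]) and not res.loc[0, "significant"]
        assert res.loc[0, "n1"] == 1

    def test_planted_effects_recovered(self):
        m, truth = generate_protein_matrix(
            500,
            {"VS": 3, "periphery": 3},
            planted_effects=[(i, 2.0) for i in range(20)],
            seed=9,
        )
        logged = log2_transform(group_completeness_filter(m).matrix)
        res, info = permutation_fdr_ttest(logged, seed=10)
        hits = set(res.loc[res["significant"], "protein_id"])
        planted = set(truth["protein_id"])
        assert len(hits & planted) / len(planted) >= 0.9
        assert info.s0 > 0


class TestMarkerPanel:
    def test_empty_panel(self):
        res = pd.DataFrame(
            {"protein_id": ["RHO"], "log2_fc": [1.0], "q_value": [0.01]}
        )
        table, missing = marker_panel_report(res, [])
        assert table.empty and missing == []

    def test_planted_marker_direction_and_missing(self):
        m, _ = generate_protein_matrix(
            100,
            {"VS": 3, "periphery": 3},
            planted_effects=[(0, 2.0)],
            seed=11,
            protein_ids=["RHO"] + [f"P{i}" for i in range(99)],
        )
        logged = log2_transform(m)
        res, _ = permutation_fdr_ttest(logged, seed=12)
        table, missing = marker_panel_report(res, ["RHO", "NOT_A_PROTEIN"])
        assert missing == ["NOT_A_PROTEIN"]
        row = table.set_index("protein_id").loc["RHO"]
        assert row["log2_fc"] > 0 and row["direction"] == "up"
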