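"""RPE mosaic geometry, median-threshold filtering and corrections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from streakmorph.rpe import (
    RPETrace,
    analyze_trace,
    classify_gaps,
    correct_binucleates,
    hexagon_area,
    hexagon_geometry,
    internuclear_distances,
    phagosomes_per_cell,
    relative_increase,
)


def trace(positions, L=250.0, region="VS"):
    return RPETrace(animal_id="A1", region=region, positions=np.asarray(positions, float),
                    segment_length=L)


class TestDistances:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([0, 20, 40, 70], [20, 20, 30]),
            (np.arange(12) * 20.0, [20.0] * 11),
            ([5, 8, 28], [3, 20]),
        ],
    )
    def test_consecutive_differences(self, positions, expected):
        np.testing.assert_allclose(internuclear_distances(trace(positions)), expected)

    def test_too_few_positions(self):
        with pytest.raises(ValueError):
            internuclear_distances(trace([10.0]))

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            trace([10.0, 10.0, 30.0])


class TestClassification:
    def test_median_thresholds_and_labels(self):
        cls = classify_gaps([20, 20, 30, 9, 41])
        assert cls.median_distance == 20
        assert (cls.lower_threshold, cls.upper_threshold) == (10, 40)
        assert list(cls.labels) == ["normal", "normal", "normal", "binucleate", "dropout"]

    def test_all_equal_gaps_are_normal(self):
        cls = classify_gaps([15.0] * 8)
        assert set(cls.labels) == {"normal"}

    def test_measured_vs_median_gives_measured_thresholds(self):
        # a median of 17.12 μm puts the artifact cuts at 8.56 and 34.24 μm
        cls = classify_gaps([17.12, 16.0, 18.0])
        assert cls.median_distance == pytest.approx(17.12)
        assert cls.lower_threshold == pytest.approx(8.56)
        assert cls.upper_threshold == pytest.approx(34.24)

    def test_boundary_gaps_are_normal(self):
        # exactly half / exactly twice the median: strict inequalities
        cls = classify_gaps([10.0, 20.0, 20.0, 40.0])
        assert list(cls.labels) == ["normal"] * 4

    def test_even_length_median_is_central_mean(self):
        cls = classify_gaps([10.0, 20.0])
        assert cls.median_distance == 15.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_gaps([])

    def test_external_pooled_median(self):
        cls = classify_gaps([9.0, 20.0], median_distance=20.0)
        assert list(cls.labels) == ["binucleate", "normal"]


class TestCorrection:
    def test_midpoint_merge(self):
        t = trace([0, 3, 23])
        cls = classify_gaps(internuclear_distances(t))
        assert list(cls.labels)[0] == "binucleate"
        corr = correct_binucleates(t, cls)
        np.testing.assert_allclose(corr.positions, [1.5, 23.0])
        np.testing.assert_allclose(corr.corrected_distances, [21.5])
        assert corr.n_merges == 1

    def test_identity_when_no_binucleates(self):
        t = trace([0, 20, 40, 60])
        cls = classify_gaps(internuclear_distances(t))
        corr = correct_binucleates(t, cls)
        np.testing.assert_allclose(corr.positions, t.positions)
        np.testing.assert_allclose(corr.corrected_distances, [20, 20, 20])

    def test_dropout_gap_excluded_but_flanks_retained(self):
        t = trace([0, 20, 110, 130, 150])
        cls = classify_gaps(internuclear_distances(t))
        assert list(cls.labels)[1] == "dropout"
        corr = correct_binucleates(t, cls)
        assert corr.positions.size == 5  # nothing silently dropped
        np.testing.assert_allclose(corr.corrected_distances, [20, 20, 20])
        assert corr.dropout_fraction == pytest.approx(1 / 4)

    def test_chain_resolved_greedily_left_to_right(self):
        # gaps [3, 3, 20, 20]: median 11.5 → both 3s binucleate; only the
        # first pair merges, the second gap is flagged as a chain conflict
        t = trace([0, 3, 6, 26, 46])
        cls = classify_gaps(internuclear_distances(t))
        corr = correct_binucleates(t, cls)
        np.testing.assert_allclose(corr.positions, [1.5, 6, 26, 46])
        assert corr.n_merges == 1
        assert corr.n_chain_conflicts == 1
        np.testing.assert_allclose(corr.corrected_distances, [4.5, 20, 20])

    def test_nucleus_conservation(self, rng):
        from streakmorph.synthetic import TruthParams, generate_rpe_trace

        p = TruthParams(
            region_name="VS", cone_rate=60, onl_rows=8.6, nucleus_diameter=5,
            os_length_mean=22, os_length_sd=2.7, rpe_spacing_mean=19.16,
            rpe_spacing_cv=0.15, binucleate_prob=0.14, dropout_prob=0.04,
            binucleate_offset=3.0, phagosome_rate=2.8, rpe_height_mean=12,
        )
        for seed in range(5):
            st_ = generate_rpe_trace(p, segment_length=2000, seed=seed)
            cls = classify_gaps(internuclear_distances(st_.trace))
            corr = correct_binucleates(st_.trace, cls)
            assert corr.n_corrected_nuclei == corr.n_raw_nuclei - corr.n_merges

    def test_remove_mode_drops_binucleate_gaps(self):
        t = trace([0, 3, 23, 43])
        cls = classify_gaps(internuclear_distances(t))
        corr = correct_binucleates(t, cls, mode="remove")
        np.testing.assert_allclose(corr.positions, t.positions)
        np.testing.assert_allclose(corr.corrected_distances, [20, 20])

    def test_filter_idempotent_on_clean_trace(self):
        t = trace([0, 18, 37, 57, 78])
        first = analyze_trace(t)
        rebuilt = np.concatenate([[0.0], first.corrected_distances.cumsum()])
        again = analyze_trace(RPETrace("A1", "VS", rebuilt, 250.0))
        assert set(again.classifications) == {"normal"}
        np.testing.assert_allclose(
            np.sort(again.corrected_distances), np.sort(first.corrected_distances)
        )

    def test_reporting_convention_fraction(self):
        # the nuclei-denominator convention: flagged gaps / raw nuclei
        t = trace([0, 3, 23, 43, 63, 83, 103])
        cls = classify_gaps(internuclear_distances(t))
        corr = correct_binucleates(t, cls)
        assert corr.binucleate_fraction == pytest.approx(1 / 7)
        assert corr.binucleate_cell_prob == pytest.approx(1 / 6)


class TestHexagonModel:
    @pytest.mark.parametrize(
        "d,expected,tol",
        [
            (19.16, 317.9, 0.05),  # visual-streak mean extension
            (0.0, 0.0, 1e-12),
            (2.0, 2 * np.sqrt(3), 1e-12),
        ],
    )
    def test_area_values(self, d, expected, tol):
        assert hexagon_area(d) == pytest.approx(expected, abs=tol)

    @staticmethod
    def shoelace_hexagon(apothem):
        # polygon-area oracle: regular hexagon with the given apothem,
        # circumradius R = 2h/√3, vertices at 60° steps
        R = 2 * apothem / np.sqrt(3)
        ang = np.arange(6) * np.pi / 3
        x, y = R * np.cos(ang), R * np.sin(ang)
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_area_matches_shoelace_oracle(self, d):
        assert hexagon_area(d) == pytest.approx(
            self.shoelace_hexagon(d / 2), rel=1e-9
        )

    @given(st.floats(min_value=0.0, max_value=1e3), st.floats(min_value=1e-6, max_value=10.0))
    def test_strictly_increasing(self, d, delta):
        assert hexagon_area(d + delta) > hexagon_area(d)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_geometry_identities(self, d):
        area, a, h = hexagon_geometry(d)
        assert h == pytest.approx(np.sqrt(3) / 2 * a, rel=1e-12)
        assert area == pytest.approx(3 * h * a, rel=1e-12)
        assert area == pytest.approx(hexagon_area(d), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hexagon_area(-1.0)


class TestRatios:
    def test_relative_increase(self):
        assert relative_increase(5.0, 5.0) == 0.0
        assert relative_increase(1.5, 1.0) == pytest.approx(50.0)
        # measured RPE heights: centre 12.08 μm vs periphery 7.0 μm
        assert relative_increase(12.08, 7.0) == pytest.approx(72.57, abs=0.01)

    def test_relative_increase_bad_reference(self):
        with pytest.raises(ValueError):
            relative_increase(1.0, 0.0)

    def test_phagosomes_per_cell(self):
        assert phagosomes_per_cell(12, 4) == 3.0
        assert phagosomes_per_cell(0, 4) == 0.0
        with pytest.raises(ValueError):
            phagosomes_per_cell(3, 0)


def test_analyze_trace_end_to_end():
    t = trace([0, 3, 23, 43, 63, 150, 170], L=250)
    res = analyze_trace(t)
    assert res.median_distance == 20.0
    assert res.lower_threshold == 10.0 and res.upper_threshold == 40.0
    assert list(res.classifications).count("binucleate") == 1
    assert list(res.classifications).count("dropout") == 1
    # corrected gaps: merged pair midpoint 1.5 → [21.5, 20, 20, (87 dropped), 20]
    np.testing.assert_allclose(np.sort(res.corrected_distances), [20, 20, 20, 21.5])
    assert res.cell_area == pytest.approx(
        hexagon_area(res.mean_corrected_distance), rel=1e-12
    )
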