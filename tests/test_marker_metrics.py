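"""Recovery/specificity/resolution metrics, PCoA and spatial-median dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markereval.marker_metrics import (MetricsError, cumulative_richness,
                                       dispersion_distances,
                                       jaccard_dissimilarity,
                                       median_absolute_deviation, pcoa_embed,
                                       recovery_by_stage, resolution_profile,
                                       spatial_median, specificity_per_sample)
from markereval.reads_pipeline import StageLog


class TestRecoveryByStage:
    def test_median_and_mad(self):
        log = StageLog()
        log.append("raw", {"a": 1, "b": 2, "c": 3})
        out = recovery_by_stage(log)
        assert out.loc["raw", "median"] == 2
        assert out.loc["raw", "mad"] == 1

    def test_all_equal_mad_zero(self):
        log = StageLog()
        log.append("raw", {"a": 7, "b": 7, "c": 7})
        assert recovery_by_stage(log).loc["raw", "mad"] == 0

    def test_five_sample_hand_computation(self):
        log = StageLog()
        log.append("raw", {s: v for s, v in zip("abcde", [10, 30, 20, 50, 40])})
        log.append("filtered", {s: v for s, v in zip("abcde", [8, 12, 14, 45, 9])})
        out = recovery_by_stage(log)
        # hand: median(10,30,20,50,40)=30; |x-30| = 20,0,10,20,10 -> MAD 10
        assert out.loc["raw", "median"] == 30 and out.loc["raw", "mad"] == 10
        # hand: median(8,12,14,45,9)=12; |x-12| = 4,0,2,33,3 -> MAD 3
        assert out.loc["filtered", "median"] == 12 and out.loc["filtered", "mad"] == 3

    def test_empty_log_raises(self):
        with pytest.raises(MetricsError):
            recovery_by_stage(StageLog())


class TestSpecificity:
    def test_fraction_non_target(self):
        flags = {"S1": [True] * 40 + [False] * 60}
        assert specificity_per_sample(flags)["S1"] == pytest.approx(0.6)

    def test_all_target_zero(self):
        assert specificity_per_sample({"S1": [True, True]})["S1"] == 0.0

    def test_empty_sample_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = specificity_per_sample({"S1": [True], "S2": []})
        assert list(out.index) == ["S1"]

    def test_three_sample_hand_tally(self):
        flags = {"S1": [True, False, False], "S2": [True] * 3 + [False],
                 "S3": [False] * 5}
        out = specificity_per_sample(flags)
        assert out["S1"] == pytest.approx(2 / 3)
        assert out["S2"] == pytest.approx(0.25)
        assert out["S3"] == pytest.approx(1.0)


class TestResolutionProfile:
    def frame(self, sample, n_order, n_family, n_genus, n_species):
        rows = []
        for i in range(n_order):
            rows.append({"sample": sample, "order_assigned": True,
                         "family_resolved": i < n_family,
                         "genus_resolved": i < n_genus,
                         "species_resolved": i < n_species})
        return pd.DataFrame(rows)

    def test_proportions(self):
        df = self.frame("S1", 100, 80, 60, 10)
        out = resolution_profile(df)
        assert out.loc["S1", "unassigned_family"] == pytest.approx(0.20)
        assert out.loc["S1", "unassigned_genus"] == pytest.approx(0.40)
        assert out.loc["S1", "unassigned_species"] == pytest.approx(0.90)

    def test_fully_resolved_zero(self):
        out = resolution_profile(self.frame("S1", 10, 10, 10, 10))
        assert out.loc["S1"].iloc[1:].tolist() == [0.0, 0.0, 0.0]

    def test_nested_ordering_invariant(self):
        out = resolution_profile(self.frame("S1", 50, 40, 25, 5))
        row = out.loc["S1"]
        assert row["unassigned_species"] >= row["unassigned_genus"] >= row["unassigned_family"]

    def test_sample_without_order_reads_excluded(self):
        df = pd.concat([self.frame("S1", 10, 5, 5, 1),
                        pd.DataFrame([{"sample": "S2", "order_assigned": False,
                                       "family_resolved": False,
                                       "genus_resolved": False,
                                       "species_resolved": False}])])
        with pytest.warns(UserWarning):
            out = resolution_profile(df)
        assert list(out.index) == ["S1"]


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
        ({"A"}, {"A"}, 0.0),
        ({"A"}, {"B"}, 1.0),
    ])
    def test_examples(self, a, b, expected):
        assert jaccard_dissimilarity(a, b) == pytest.approx(expected)

    def test_both_empty_raises(self):
        with pytest.raises(MetricsError):
            jaccard_dissimilarity(set(), set())

    @given(st.tuples(*[st.sets(st.integers(0, 8)) for _ in range(3)]))
    @settings(max_examples=60, deadline=None)
    def test_triangle_inequality(self, sets):
        a, b, c = sets
        if not (a | b) or not (b | c) or not (a | c):
            return
        dab = jaccard_dissimilarity(a, b)
        dbc = jaccard_dissimilarity(b, c)
        dac = jaccard_dissimilarity(a, c)
        assert dac <= dab + dbc + 1e-12


class TestPcoa:
    def test_equilateral_distances_reproduced(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = pcoa_embed(d)
        pts = emb.positive
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(1.0, abs=1e-8)

    def test_identical_items_coincide(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        emb = pcoa_embed(d)
        assert np.allclose(emb.positive[0], emb.positive[1], atol=1e-9)

    def test_euclidean_input_nonnegative_eigenvalues(self, rng):
        pts = rng.random((4, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = pcoa_embed(d)
        assert (emb.eigenvalues >= -1e-10).all()
        assert emb.negative.shape[1] == 0

    def test_euclidean_distance_reproduction(self, rng):
        for _ in range(10):
            pts = rng.random((6, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            emb = pcoa_embed(d)
            got = np.linalg.norm(emb.positive[:, None] - emb.positive[None, :], axis=-1)
            assert np.allclose(got, d, atol=1e-8)

    def test_matches_skbio_on_euclidean_input(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.random((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = pcoa_embed(d)
        ref = skbio_pcoa(d, number_of_dimensions=2)
        mine = np.sort(emb.eigenvalues)[::-1][:2]
        theirs = np.sort(ref.eigvals.to_numpy())[::-1][:2]
        assert np.allclose(mine, theirs, atol=1e-8)

    def test_asymmetric_raises(self):
        with pytest.raises(MetricsError):
            pcoa_embed(np.array([[0, 1.0], [0.5, 0]]))


class TestSpatialMedian:
    def test_identical_points(self):
        pts = np.tile([1.0, 2.0], (4, 1))
        assert np.allclose(spatial_median(pts), [1.0, 2.0])

    def test_square_centre_by_symmetry(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        assert np.allclose(spatial_median(pts), [0.5, 0.5], atol=1e-7)

    def test_collinear_is_one_dimensional_median(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        assert spatial_median(pts)[0] == pytest.approx(1.0, abs=1e-6)

    def test_objective_not_worse_than_candidates(self, rng):
        pts = rng.random((6, 3))
        med = spatial_median(pts)

        def obj(x):
            return np.linalg.norm(pts - x, axis=1).sum()

        best = obj(med)
        for p in pts:
            assert best <= obj(p) + 1e-9
        cands = rng.random((10_000, 3))
        assert best <= np.linalg.norm(pts[None] - cands[:, None], axis=-1).sum(axis=1).min() + 1e-9


class TestDispersionDistances:
    def test_identical_sets_zero_distance(self):
        sets = {"g1": {m: {"A", "B"} for m in "wxyz"}}
        out = dispersion_distances(sets)
        assert np.allclose(out.distances.loc["g1"].to_numpy(), 0.0, atol=1e-9)

    def test_disjoint_marker_has_largest_distance(self):
        sets = {"g1": {"w": {"A", "B"}, "x": {"A", "B"}, "y": {"A", "B"},
                       "z": {"Q", "R"}}}
        row = dispersion_distances(sets).distances.loc["g1"]
        assert row["z"] > max(row[m] for m in "wxy")

    def test_group_with_single_marker_skipped(self):
        with pytest.warns(UserWarning):
            out = dispersion_distances({"g1": {"w": {"A"}}})
        assert len(out.distances) == 0


class TestCumulativeRichness:
    def test_pooled_union(self):
        per_pool, total = cumulative_richness(
            {"s1": {"A", "B"}, "s2": {"B", "C"}}, {"s1": "p1", "s2": "p1"})
        assert per_pool["p1"] == 3
        assert total == 3

    def test_empty_samples(self):
        per_pool, total = cumulative_richness({"s1": set()}, {"s1": "p1"})
        assert per_pool["p1"] == 0 and total == 0

    def test_missing_sample_raises(self):
        with pytest.raises(MetricsError):
            cumulative_richness({"s1": {"A"}}, {})

    def test_cross_pool_total(self):
        per_pool, total = cumulative_richness(
            {"s1": {"A"}, "s2": {"B"}, "s3": {"A", "C"}},
            {"s1": "p1", "s2": "p1", "s3": "p2"})
        assert per_pool["p1"] == 2 and per_pool["p2"] == 2
        assert total == 3


class TestMad:
    def test_unscaled(self):
        assert median_absolute_deviation(np.array([1.0, 2.0, 3.0])) == 1.0
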