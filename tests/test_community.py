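"""Abundance-matrix pipeline, diversity, dissimilarity, clustering, Mantel."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from cryoviromics import community


class TestPresenceRule:
    def test_breadth_boundary_inclusive(self, coverage_frame):
        matrix = community.apply_presence_rule(coverage_frame)
        assert matrix.loc["g1", "s1"] == 500  # breadth 0.80 kept
        assert matrix.loc["g1", "s2"] == 0  # breadth 0.74 zeroed
        assert matrix.loc["g2", "s1"] == 500  # breadth exactly 0.75 kept

    def test_missing_pairs_are_zero(self, coverage_frame):
        matrix = community.apply_presence_rule(coverage_frame.iloc[:3])
        assert matrix.loc["g2", "s2"] == 0

    def test_stage_tag(self, coverage_frame):
        assert community.apply_presence_rule(coverage_frame).attrs["stage"] == "presence-filtered"


class TestLengthLibraryNormalize:
    def test_length_ratio(self):
        matrix = pd.DataFrame({"s1": [100.0, 100.0]}, index=["a", "b"])
        out = community.length_library_normalize(matrix, {"a": 10_000, "b": 20_000})
        assert out.loc["a", "s1"] / out.loc["b", "s1"] == pytest.approx(2.0)

    def test_library_scaling_invariance(self):
        matrix = pd.DataFrame({"s1": [100.0, 300.0], "s2": [200.0, 600.0]}, index=["a", "b"])
        out = community.length_library_normalize(matrix, {"a": 1000, "b": 1000})
        # doubling every count in a sample changes nothing after per-library scaling
        assert np.allclose(out["s1"], out["s2"])

    def test_all_zero_sample_dropped(self):
        matrix = pd.DataFrame({"s1": [10.0, 5.0], "s2": [0.0, 0.0]}, index=["a", "b"])
        out = community.length_library_normalize(matrix, {"a": 1000, "b": 1000})
        assert list(out.columns) == ["s1"]


class TestCssNormalize:
    def test_identical_samples_identical_output(self):
        matrix = pd.DataFrame({"s1": [5.0, 10, 20, 40], "s2": [5.0, 10, 20, 40]}, index=list("abcd"))
        out = community.css_normalize(matrix)
        assert np.allclose(out["s1"], out["s2"])

    def test_scale_invariance_at_fixed_quantile(self):
        matrix = pd.DataFrame({"s1": [5.0, 10, 20, 40], "s2": [50.0, 100, 200, 400]}, index=list("abcd"))
        out = community.css_normalize(matrix)
        assert np.allclose(out["s1"], out["s2"])

    def test_hand_worked_factor_is_sum_of_two_smallest(self):
        # 4 distinct non-zero counts at q=0.5: the median of {3,7,20,50}
        # interpolates between 7 and 20, so counts <= it are {3, 7}
        matrix = pd.DataFrame({"s1": [3.0, 7.0, 20.0, 50.0]}, index=list("abcd"))
        out = community.css_normalize(matrix, quantile=0.5, scale=1000.0)
        assert out.loc["a", "s1"] == pytest.approx(3.0 / 10.0 * 1000.0)

    def test_css_is_idempotent(self, rng):
        matrix = pd.DataFrame(rng.poisson(20, size=(30, 4)).astype(float))
        once = community.css_normalize(matrix)
        twice = community.css_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_sparse_sample_falls_back_to_library_sum(self):
        matrix = pd.DataFrame({"s1": [9.0, 0.0, 0.0, 0.0]}, index=list("abcd"))
        out = community.css_normalize(matrix)
        assert out.loc["a", "s1"] == pytest.approx(1000.0)


class TestDiversity:
    def test_single_species_has_zero_shannon(self):
        assert community.shannon([10.0]) == pytest.approx(0.0)

    def test_uniform_ten_species(self):
        assert community.shannon([1.0] * 10) == pytest.approx(math.log(10), abs=1e-9)

    def test_two_even_species(self):
        assert community.shannon([0.5, 0.5]) == pytest.approx(0.6931, abs=1e-4)

    def test_uniform_community_evenness_is_one(self):
        assert community.pielou([2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_hand_computed_evenness(self):
        assert community.pielou([0.5, 0.25, 0.25]) == pytest.approx(0.946, abs=1e-3)

    def test_richness_one_is_undefined(self):
        assert math.isnan(community.pielou([5.0, 0.0]))

    def test_shannon_maximal_at_uniform(self, rng):
        for _ in range(20):
            v = rng.random(8) + 0.01
            assert community.shannon(v) <= math.log(8) + 1e-12

    def test_diversity_table_bounds(self, rng):
        matrix = pd.DataFrame(rng.poisson(10, size=(30, 5)).astype(float))
        table = community.diversity_table(matrix)
        assert ((table["pielou_j"] >= 0) & (table["pielou_j"] <= 1)).all()


class TestBrayCurtis:
    def test_identical_samples_give_zero(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        assert community.bray_curtis(m).loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_samples_give_one(self):
        m = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]})
        assert community.bray_curtis(m).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        m = pd.DataFrame({"u": [1.0, 1.0, 0.0], "v": [0.0, 1.0, 1.0]})
        assert community.bray_curtis(m).loc["u", "v"] == pytest.approx(0.5)

    def test_symmetry_and_bounds(self, rng):
        m = pd.DataFrame(rng.random((20, 6)) + 0.01)
        d = community.bray_curtis(m)
        assert np.allclose(d.values, d.values.T)
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(np.diag(d.values), 0.0)


class TestHierarchicalCluster:
    def test_clear_pair_merges_first(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        z, labels, newick = community.hierarchical_cluster(d)
        assert z[0, 2] == pytest.approx(0.1)  # first merge at the close pair
        assert "(a:0.1,b:0.1)" in newick

    def test_ultrametric_input_reproduced_by_average_linkage(self):
        # build an ultrametric: ((a,b):h1, (c,d):h1):h2 pattern
        d = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        frame = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        z, labels, _ = community.hierarchical_cluster(frame)
        cophenetic = squareform(hierarchy.cophenet(z))
        assert np.allclose(cophenetic, d)

    def test_planted_two_region_scenario_splits_at_top(self, rng):
        # two groups of samples with disjoint dominant genomes
        block = np.zeros((20, 6))
        block[:10, :3] = rng.poisson(50, size=(10, 3))
        block[10:, 3:] = rng.poisson(50, size=(10, 3))
        block += rng.poisson(1, size=(20, 6))
        m = pd.DataFrame(block, columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        d = community.bray_curtis(m)
        z, labels, _ = community.hierarchical_cluster(d)
        top = hierarchy.fcluster(z, t=2, criterion="maxclust")
        split = {tuple(sorted(np.array(labels)[top == c])) for c in (1, 2)}
        assert split == {("A1", "A2", "A3"), ("B1", "B2", "B3")}


class TestMantel:
    def _random_distance(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_identical_matrices_give_r_one(self, rng):
        d = self._random_distance(rng, 8)
        result = community.mantel(d, d, n_permutations=99, seed=0)
        assert result.r == pytest.approx(1.0)
        assert result.p <= 0.05

    def test_reversed_matrix_gives_r_minus_one(self, rng):
        d = self._random_distance(rng, 8)
        flipped = d.max() - d
        np.fill_diagonal(flipped, 0.0)
        result = community.mantel(d, flipped, n_permutations=99, seed=0)
        assert result.r == pytest.approx(-1.0)

    def test_seed_determinism(self, rng):
        a, b = self._random_distance(rng, 10), self._random_distance(rng, 10)
        r1 = community.mantel(a, b, seed=5)
        r2 = community.mantel(a, b, seed=5)
        assert r1 == r2

    def test_matches_skbio_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a, b = self._random_distance(rng, 12), self._random_distance(rng, 12)
        ours = community.mantel(a, b, n_permutations=99, seed=0)
        theirs_r, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a), skbio_distance.DistanceMatrix(b), permutations=0
        )
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-9)

    def test_order_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            community.mantel(self._random_distance(rng, 5), self._random_distance(rng, 6))


class TestRelativeAbundanceFilter:
    def test_exactly_at_threshold_dropped(self):
        m = pd.DataFrame({"s1": [1.0, 99.0], "s2": [1.0, 99.0]}, index=["low", "high"])
        out = community.filter_relative_abundance(m, threshold=0.01)
        assert list(out.index) == ["high"]

    def test_kept_if_abundant_in_any_sample(self):
        m = pd.DataFrame({"s1": [5.0, 95.0], "s2": [0.1, 99.9]}, index=["spiky", "high"])
        out = community.filter_relative_abundance(m, threshold=0.01)
        assert "spiky" in out.index

    def test_empty_result_allowed(self):
        m = pd.DataFrame({"s1": [50.0, 50.0]}, index=["a", "b"])
        out = community.filter_relative_abundance(m, threshold=0.9)
        assert out.empty
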