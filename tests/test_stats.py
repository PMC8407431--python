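"""Effect sizes, rank tests, and the compact letter display.

Exact expectations come from hand computation or exhaustive enumeration;
the enumeration oracle for the rank-sum test lives in this module so the
tested path (scipy-backed) and the oracle stay independent.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoviromics import stats


def exact_rank_sum_p(x, y):
    """Exhaustive two-sided rank-sum p: enumerate all group assignments."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    observed = sum(ranks[v] for v in x)
    n = len(x)
    sums = [sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(sums)
    tail = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return tail / len(sums)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        assert stats.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        # means 10 and 8, both variances 8, pooled SD = 2.8284
        assert stats.cohens_d([8, 12], [6, 10]) == pytest.approx(0.7071, abs=1e-4)

    def test_antisymmetry(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 5.0, 8.0]
        assert stats.cohens_d(a, b) == pytest.approx(-stats.cohens_d(b, a))

    def test_zero_pooled_sd_unequal_means_is_undefined(self):
        assert math.isnan(stats.cohens_d([1.0, 1.0], [2.0, 2.0]))

    def test_zero_pooled_sd_equal_means_is_zero(self):
        assert stats.cohens_d([2.0, 2.0], [2.0, 2.0]) == 0.0

    def test_groups_of_one_rejected(self):
        with pytest.raises(ValueError):
            stats.cohens_d([1.0], [2.0, 3.0])


class TestCommonLanguageEffect:
    def test_zero_effect_is_a_coin_flip(self):
        assert stats.common_language_effect(0.0) == pytest.approx(0.5)

    def test_reported_hydrophobicity_effect(self):
        # d = 0.45 corresponds to a 62.5% probability of superiority
        assert round(stats.common_language_effect(0.45), 3) == 0.625

    def test_reported_molecular_weight_effect(self):
        # d = 0.32 corresponds to a 59% probability of superiority
        assert round(stats.common_language_effect(0.32), 2) == 0.59

    @given(st.floats(min_value=-3, max_value=3), st.floats(min_value=-3, max_value=3))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_d(self, d1, d2):
        if d1 + 1e-9 < d2:  # differences below float resolution excluded
            assert stats.common_language_effect(d1) < stats.common_language_effect(d2)

    def test_infinite_d_rejected(self):
        with pytest.raises(ValueError):
            stats.common_language_effect(float("nan"))


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = stats.kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert h == 0.0 and p == 1.0

    def test_matches_explicit_rank_computation(self):
        groups = [[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]]
        h, _ = stats.kruskal_wallis(groups)
        # oracle: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        pooled = np.concatenate(groups)
        ranks = pooled.argsort().argsort() + 1
        n = len(pooled)
        r1, r2 = ranks[:3].mean(), ranks[3:].mean()
        expected = 12.0 / (n * (n + 1)) * (3 * (r1 - (n + 1) / 2) ** 2 + 3 * (r2 - (n + 1) / 2) ** 2)
        assert h == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        groups = {"a": [1.0, 5.0, 9.0], "b": [2.0, 3.0, 11.0], "c": [4.0, 8.0, 10.0]}
        h1, p1 = stats.kruskal_wallis(groups)
        transformed = {k: [math.exp(v) for v in vs] for k, vs in groups.items()}
        h2, p2 = stats.kruskal_wallis(transformed)
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)


class TestPairwiseWilcoxon:
    def test_exact_disjoint_triplets(self):
        mat = stats.pairwise_wilcoxon({"a": [1, 2, 3], "b": [4, 5, 6]}, correction="none")
        assert mat.loc["a", "b"] == pytest.approx(0.1)

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(10):
            # even vs odd integers: tie-free by construction
            x = rng.choice(50, size=5, replace=False).astype(float) * 2
            y = rng.choice(50, size=6, replace=False).astype(float) * 2 + 1
            mat = stats.pairwise_wilcoxon({"x": x, "y": y}, correction="none")
            assert mat.loc["x", "y"] == pytest.approx(exact_rank_sum_p(x, y))

    def test_group_against_itself_is_one(self):
        mat = stats.pairwise_wilcoxon({"a": [1, 2, 3], "b": [1, 2, 3]}, correction="none")
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        groups = {k: rng.normal(size=30) for k in "abc"}
        mat = stats.pairwise_wilcoxon(groups)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_holm_adjustment_never_lowers_p(self, rng):
        groups = {k: rng.normal(loc=i, size=25) for i, k in enumerate("abcd")}
        raw = stats.pairwise_wilcoxon(groups, correction="none")
        adj = stats.pairwise_wilcoxon(groups, correction="holm")
        off = ~np.eye(4, dtype=bool)
        assert (adj.values[off] >= raw.values[off] - 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.pairwise_wilcoxon({"a": [], "b": [1.0]})


def _p_matrix(labels, sig_pairs):
    labels = list(labels)
    mat = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in sig_pairs:
        mat.loc[a, b] = mat.loc[b, a] = 0.001
    return mat


class TestCompactLetterDisplay:
    def test_no_significant_pairs_share_one_letter(self):
        letters = stats.compact_letter_display(_p_matrix("ABC", []), alpha=0.01)
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_get_distinct_letters(self):
        letters = stats.compact_letter_display(
            _p_matrix("ABC", [("A", "B"), ("A", "C"), ("B", "C")]), alpha=0.01
        )
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_case_gives_bridging_letters(self):
        # A != C significant; A-B and B-C not: the standard a / ab / b pattern
        letters = stats.compact_letter_display(_p_matrix("ABC", [("A", "C")]), alpha=0.01)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_every_group_has_a_letter(self, rng):
        labels = list("ABCDE")
        pairs = [(a, b) for a, b in itertools.combinations(labels, 2) if rng.random() < 0.5]
        letters = stats.compact_letter_display(_p_matrix(labels, pairs), alpha=0.01)
        assert all(letters[lab] for lab in labels)

    def test_sharing_iff_not_significant(self, rng):
        # consistency: significantly different groups never share a letter,
        # and non-different pairs share at least one letter in these cases
        for pairs in [[("A", "B")], [("A", "C"), ("B", "C")], []]:
            mat = _p_matrix("ABC", pairs)
            letters = stats.compact_letter_display(mat, alpha=0.01)
            for a, b in itertools.combinations("ABC", 2):
                share = set(letters[a]) & set(letters[b])
                if (a, b) in pairs:
                    assert not share
                else:
                    assert share


class TestEffectSizeTable:
    def test_sign_convention_other_minus_reference(self, rng):
        frame = pd.DataFrame(
            {
                "region": ["SO"] * 50 + ["WARM"] * 50,
                "hy": np.r_[rng.normal(-0.4, 0.3, 50), rng.normal(-0.1, 0.3, 50)],
            }
        )
        table = stats.effect_size_table(frame, ["hy"], reference="SO")
        assert table["d_region_minus_reference"].iloc[0] > 0
        assert table["cl"].iloc[0] > 0.5

    def test_average_abs_d_is_unweighted_mean(self):
        effects = pd.DataFrame(
            {
                "property": ["hy", "hy"],
                "d_region_minus_reference": [0.5, -0.3],
            }
        )
        assert stats.average_abs_d(effects, "hy") == pytest.approx(0.4)
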