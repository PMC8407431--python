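"""Region-comparison statistics for proteome properties.

Cohen's d with the normal-theory probability of superiority, Kruskal-Wallis,
pairwise Wilcoxon rank-sum with multiple-testing correction, and a compact
letter display (insert-and-absorb) for figure-style group labels.

Sign convention for regional effect sizes: d = (other region - reference
region) / pooled SD, so a positive d for hydrophobicity means the reference
(e.g. Southern Ocean) proteome is *less* hydrophobic. The convention is
carried in output headers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectSizeResult",
    "cohens_d",
    "common_language_effect",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "compact_letter_display",
    "effect_size_table",
    "average_abs_d",
    "group_comparison_table",
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized mean difference between two groups plus its
    probability-of-superiority reading (cl = Phi(d / sqrt(2)))."""

    property: str
    group_a: str
    group_b: str
    d: float
    cl: float
    n_a: int
    n_b: int


def cohens_d(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD.

    Pooled SD uses the Bessel-corrected group variances weighted by their
    degrees of freedom. Degenerate case: zero pooled SD returns 0 when the
    means are also equal, NaN (undefined) otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        return 0.0 if diff == 0 else math.nan
    return float(diff / math.sqrt(pooled_var))


def common_language_effect(d: float) -> float:
    """Probability of superiority under normal theory: Phi(d / sqrt(2)).

    The chance that a random draw from the higher-mean group exceeds an
    independent random draw from the other group, assuming two normal
    populations with equal variance separated by d pooled SDs.
    """
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return float(sps.norm.cdf(d / math.sqrt(2.0)))


def kruskal_wallis(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    All-identical values are a degenerate rank configuration: H = 0, p = 1.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for _, v in sorted(groups.items())]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one pair.

    Exact null enumeration when both groups are small (n <= 20) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    ties = np.intersect1d(x, y).size > 0 or np.unique(x).size < x.size or np.unique(y).size < y.size
    if max(x.size, y.size) <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    correction: str = "holm",
) -> pd.DataFrame:
    """Symmetric matrix of (adjusted) two-sided rank-sum p-values.

    ``correction`` is any statsmodels ``multipletests`` method, or ``"none"``
    to report raw p-values. Diagonal is 1 by construction.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"empty group {k!r}")
    pairs = list(itertools.combinations(labels, 2))
    raw = np.array([_rank_sum_p(arrays[a], arrays[b]) for a, b in pairs])
    if correction != "none" and len(raw):
        adjusted = multipletests(raw, method=correction)[1]
    else:
        adjusted = raw
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    np.fill_diagonal(mat.values, 1.0)
    for (a, b), p in zip(pairs, adjusted):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def compact_letter_display(p_matrix: pd.DataFrame, alpha: float = 0.01) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups that are *not* significantly different (p >= alpha) may share a
    letter; groups sharing no letter differ significantly. Deterministic:
    significant pairs are processed in lexicographic order and letter
    columns are ordered by their sorted member sets.
    """
    labels = sorted(p_matrix.index)
    columns: list[set[str]] = [set(labels)]
    sig_pairs = sorted(
        (a, b)
        for a, b in itertools.combinations(labels, 2)
        if p_matrix.loc[a, b] < alpha
    )
    for a, b in sig_pairs:
        expanded: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                expanded.append(col - {a})
                expanded.append(col - {b})
            else:
                expanded.append(col)
        # absorb: drop empties, duplicates, and proper subsets
        kept: list[set[str]] = []
        for col in expanded:
            if not col or col in kept:
                continue
            if any(col < other for other in expanded):
                continue
            kept.append(col)
        columns = kept
    columns.sort(key=lambda c: tuple(sorted(c)))
    letters = {lab: "" for lab in labels}
    for letter, col in zip(_letter_stream(), columns):
        for lab in sorted(col):
            letters[lab] += letter
    return letters


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


# -- table-level helpers -----------------------------------------------------

def effect_size_table(
    properties: pd.DataFrame,
    value_columns: Sequence[str],
    reference: str = "SO",
) -> pd.DataFrame:
    """Effect sizes of every other region versus the reference region.

    One row per (property, region) pair with d = (region - reference)
    standardized by the pooled SD, and cl = Phi(d / sqrt(2)).
    """
    regions = sorted(properties["region"].unique())
    if reference not in regions:
        raise ValueError(f"reference region {reference!r} absent from data")
    ref_mask = properties["region"] == reference
    rows = []
    for col in value_columns:
        ref_vals = properties.loc[ref_mask, col].to_numpy(dtype=float)
        for region in regions:
            if region == reference:
                continue
            other = properties.loc[properties["region"] == region, col].to_numpy(dtype=float)
            d = cohens_d(other, ref_vals)
            rows.append(
                {
                    "property": col,
                    "region": region,
                    "reference": reference,
                    "d_region_minus_reference": d,
                    "cl": common_language_effect(d) if math.isfinite(d) else math.nan,
                    "n_region": other.size,
                    "n_reference": ref_vals.size,
                }
            )
    return pd.DataFrame(rows)


def average_abs_d(effects: pd.DataFrame, property_name: str) -> float:
    """Unweighted mean of |d| across region-versus-reference pairs."""
    sub = effects.loc[effects["property"] == property_name, "d_region_minus_reference"]
    if sub.empty:
        raise ValueError(f"no effect rows for property {property_name!r}")
    return float(sub.abs().mean())


def group_comparison_table(
    properties: pd.DataFrame,
    value_columns: Sequence[str],
    alpha: float = 0.01,
    correction: str = "holm",
) -> pd.DataFrame:
    """Kruskal-Wallis plus pairwise-Wilcoxon letter groups per property."""
    regions = sorted(properties["region"].unique())
    rows = []
    for col in value_columns:
        groups = {
            r: properties.loc[properties["region"] == r, col].to_numpy(dtype=float)
            for r in regions
        }
        h, p = kruskal_wallis(groups)
        letters = compact_letter_display(pairwise_wilcoxon(groups, correction=correction), alpha=alpha)
        row = {"property": col, "kw_statistic": h, "kw_p": p}
        for r in regions:
            row[f"letters_{r}"] = letters[r]
        rows.append(row)
    return pd.DataFrame(rows)
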