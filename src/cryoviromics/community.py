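"""Community ecology on coverage-filtered viral abundance matrices.

The pipeline the module implements, in order:

1. presence rule — a genome counts as present in a sample only with >= 1x
   depth across >= 75% of its length (breadth filter); otherwise abundance 0;
2. length and library normalization — reads per kilobase of genome per
   million retained reads;
3. cumulative-sum scaling (CSS) — per-sample scaling by the cumulative count
   up to a quantile of the non-zero counts, damping dominance by a few
   highly abundant genomes.

On the resulting matrix: Shannon H' and Pielou J diversity, Bray-Curtis
dissimilarity, average-linkage hierarchical clustering (Newick export), a
seeded Mantel permutation test, and the >1%-relative-abundance display
filter. Matrices are DataFrames with genomes as rows and samples as columns;
each stage records its tag in ``DataFrame.attrs["stage"]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("cryoviromics")

__all__ = [
    "MantelResult",
    "apply_presence_rule",
    "length_library_normalize",
    "css_normalize",
    "shannon",
    "pielou",
    "diversity_table",
    "bray_curtis",
    "hierarchical_cluster",
    "linkage_to_newick",
    "mantel",
    "environment_distance",
    "filter_relative_abundance",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


def apply_presence_rule(
    coverage: pd.DataFrame,
    breadth_threshold: float = 0.75,
) -> pd.DataFrame:
    """Genome x sample read-count matrix with the breadth presence filter.

    Counts are kept where ``breadth_1x >= breadth_threshold`` (inclusive,
    "at least"), zeroed otherwise. Missing (genome, sample) pairs are zero.
    """
    if not 0 <= breadth_threshold <= 1:
        raise ValueError("breadth_threshold must be in [0, 1]")
    kept = coverage["read_count"].where(coverage["breadth_1x"] >= breadth_threshold, 0)
    frame = coverage.assign(_kept=kept).pivot_table(
        index="genome_id", columns="sample_id", values="_kept", fill_value=0, aggfunc="sum"
    )
    frame = frame.sort_index(axis=0).sort_index(axis=1).astype(float)
    frame.attrs["stage"] = "presence-filtered"
    return frame


def length_library_normalize(
    matrix: pd.DataFrame,
    genome_lengths: pd.Series | dict,
    per_kb: float = 1_000.0,
    per_reads: float = 1_000_000.0,
) -> pd.DataFrame:
    """Reads per ``per_kb`` of genome per ``per_reads`` retained reads.

    Each cell is divided by the genome length (scaled to kilobases) and then
    by its sample's retained-read total (scaled to per-million). All-zero
    samples are dropped with a warning.
    """
    lengths = pd.Series(genome_lengths).reindex(matrix.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"missing genome lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    library_sizes = matrix.sum(axis=0)
    empty = library_sizes[library_sizes == 0].index
    if len(empty):
        logger.warning("dropping all-zero samples: %s", list(empty))
        matrix = matrix.drop(columns=empty)
        library_sizes = library_sizes.drop(empty)
    rate = matrix.div(lengths / per_kb, axis=0)
    out = rate.div(library_sizes / per_reads, axis=1)
    out.attrs["stage"] = "length-library-normalized"
    return out


def css_normalize(matrix: pd.DataFrame, quantile: float = 0.5, scale: float = 1_000.0) -> pd.DataFrame:
    """Cumulative-sum scaling per sample.

    The scaling factor of a sample is the sum of its counts that are <= the
    ``quantile``-th quantile of its *non-zero* counts; cells are divided by
    the factor and multiplied by ``scale``. A sample with fewer than two
    non-zero values falls back to its total sum as the factor (logged).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    out = matrix.copy().astype(float)
    for sample in out.columns:
        col = out[sample].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size < 2:
            factor = col.sum()
            logger.info("CSS fallback to library sum for sample %s (<2 non-zero values)", sample)
        else:
            cutoff = np.quantile(nonzero, quantile)
            factor = col[col <= cutoff].sum()
        if factor <= 0:
            raise ValueError(f"non-positive CSS factor for sample {sample}")
        out[sample] = col / factor * scale
    out.attrs["stage"] = "css-normalized"
    out.attrs["css_quantile"] = quantile
    out.attrs["css_scale"] = scale
    return out


def shannon(abundances: Sequence[float], base: float = math.e) -> float:
    """Shannon-Wiener H' = -sum p_i log p_i over non-zero proportions (nats
    by default; the log base is configurable)."""
    v = np.asarray(abundances, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = v[v > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def pielou(abundances: Sequence[float]) -> float:
    """Pielou evenness J = H' / ln(richness); undefined (NaN) below 2 species."""
    v = np.asarray(abundances, dtype=float)
    richness = int((v > 0).sum())
    if richness < 2:
        return math.nan
    return shannon(v) / math.log(richness)


def diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon H' (nats), and Pielou J."""
    rows = []
    for sample in matrix.columns:
        v = matrix[sample].to_numpy(dtype=float)
        richness = int((v > 0).sum())
        rows.append(
            {
                "sample_id": sample,
                "richness": richness,
                "shannon_h": shannon(v) if richness else math.nan,
                "pielou_j": pielou(v),
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity of matrix columns.

    BC(u, v) = 1 - 2 * sum(min(u_i, v_i)) / (sum u + sum v), in [0, 1].
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cols = matrix.to_numpy(dtype=float).T
    if (cols.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample in matrix")
    condensed = pdist(cols, metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=matrix.columns, columns=matrix.columns)


def hierarchical_cluster(
    distance: pd.DataFrame,
    linkage: str = "average",
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of a distance matrix.

    Samples are ordered lexicographically before linkage so that ties break
    deterministically by leaf label. Returns (scipy linkage matrix, leaf
    labels, Newick string with branch lengths from merge heights).
    """
    if distance.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    labels = sorted(distance.index)
    d = distance.loc[labels, labels]
    z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method=linkage)
    return z, labels, linkage_to_newick(z, labels)


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as Newick; branch length = parent merge
    height minus child merge height (leaves sit at height 0)."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def _as_square(d) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    return arr


def mantel(
    dist_a,
    dist_b,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The correlation is taken over lower-triangle entries; the p-value is the
    one-sided permutation probability (1 + #{r_perm >= r_obs}) /
    (1 + n_permutations), permuting rows and columns of the second matrix
    jointly. If both arguments are DataFrames, the second is aligned to the
    first's labels before comparison.
    """
    if isinstance(dist_a, pd.DataFrame) and isinstance(dist_b, pd.DataFrame):
        if set(dist_a.index) != set(dist_b.index):
            raise ValueError("distance matrices have different sample sets")
        dist_b = dist_b.loc[dist_a.index, dist_a.index]
    a = _as_square(dist_a)
    b = _as_square(dist_b)
    if a.shape != b.shape:
        raise ValueError("distance matrices must have the same order")
    n = a.shape[0]
    tri = np.tril_indices(n, k=-1)
    x = a[tri]
    y = b[tri]
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_perm = b[np.ix_(perm, perm)][tri]
        r_perm = float(np.corrcoef(x, y_perm)[0, 1])
        if alternative == "greater":
            extreme = r_perm >= r_obs
        elif alternative == "two-sided":
            extreme = abs(r_perm) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        hits += extreme
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations)


def environment_distance(metadata: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Euclidean distance between samples on z-scored environmental variables."""
    missing = [v for v in variables if v not in metadata.columns]
    if missing:
        raise ValueError(f"environmental variables missing from metadata: {missing}")
    values = metadata[list(variables)].to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / sd
    d = squareform(pdist(z, metric="euclidean"))
    ids = metadata["sample_id"].tolist()
    return pd.DataFrame(d, index=ids, columns=ids)


def filter_relative_abundance(matrix: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep genomes whose within-sample relative abundance is strictly above
    ``threshold`` in at least one sample (display filter for the dominant
    community members)."""
    rel = matrix.div(matrix.sum(axis=0), axis=1)
    keep = (rel > threshold).any(axis=1)
    if not keep.any():
        logger.warning("relative-abundance filter at %.3g removed every genome", threshold)
    out = matrix.loc[keep]
    out.attrs.update(matrix.attrs)
    return out
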