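"""Protein-cluster overrepresentation between a focal region and the rest.

Carriage frequency of a cluster in a genome pool is the proportion of
genomes encoding at least one member protein (a genome counts once no
matter how many copies it carries). Clusters carried by fewer than
``min_size`` genomes in the whole data set are excluded up front; among the
rest, a cluster is overrepresented when its focal-pool frequency is at
least ``ratio_threshold`` times the pooled frequency of all other regions.

Clusters absent from the non-focal pool get no finite ratio; they are
reported as focal-exclusive and kept out of the ratio mean/SD summary
rather than polluting it with infinities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ClusterMembership

__all__ = [
    "EnrichmentSummary",
    "cluster_frequencies",
    "overrepresented_clusters",
]


@dataclass(frozen=True)
class EnrichmentSummary:
    n_clusters_tested: int
    n_overrepresented: int
    n_so_exclusive: int
    mean_ratio: float
    sd_ratio: float


def cluster_frequencies(
    memberships: Iterable[ClusterMembership] | pd.DataFrame,
    genome_regions: Mapping[str, str],
    so_label: str = "SO",
    clustered_only: bool = False,
) -> pd.DataFrame:
    """Per-cluster carriage frequencies in the focal and pooled-other pools.

    ``genome_regions`` maps every genome in the data set to its region and
    defines the pool denominators. With ``clustered_only=True`` the
    denominators count only genomes appearing in at least one cluster.

    Returns columns: cluster_id, n_members_total, f_so, f_ocean.
    """
    if isinstance(memberships, pd.DataFrame):
        pairs = memberships[["cluster_id", "genome_id"]].drop_duplicates()
        grouped: dict[str, set[str]] = {
            str(cid): set(sub["genome_id"]) for cid, sub in pairs.groupby("cluster_id", sort=True)
        }
    else:
        grouped = {m.cluster_id: {g for g, _ in m.members} for m in memberships}
    unmapped = sorted({g for gs in grouped.values() for g in gs} - set(genome_regions))
    if unmapped:
        raise ValueError(f"genomes without a region label: {unmapped[:5]}")
    if clustered_only:
        universe = {g for gs in grouped.values() for g in gs}
    else:
        universe = set(genome_regions)
    so_pool = {g for g in universe if genome_regions[g] == so_label}
    ocean_pool = universe - so_pool
    if not so_pool or not ocean_pool:
        raise ValueError(f"empty genome pool (focal region {so_label!r})")
    rows = []
    for cluster_id in sorted(grouped):
        carriers = grouped[cluster_id] & universe
        n_so = len(carriers & so_pool)
        n_ocean = len(carriers) - n_so
        rows.append(
            {
                "cluster_id": cluster_id,
                "n_members_total": len(carriers),
                "f_so": n_so / len(so_pool),
                "f_ocean": n_ocean / len(ocean_pool),
            }
        )
    return pd.DataFrame(rows)


def overrepresented_clusters(
    frequencies: pd.DataFrame,
    min_size: int = 50,
    ratio_threshold: float = 5.0,
    pseudo_count: bool = False,
    n_so_pool: int | None = None,
    n_ocean_pool: int | None = None,
) -> tuple[pd.DataFrame, EnrichmentSummary]:
    """Flag clusters whose focal frequency is >= ``ratio_threshold`` times
    the pooled-other frequency, after the ``min_size`` carrier filter.

    ``pseudo_count=True`` adds one carrier to each pool before taking the
    ratio (requires the pool sizes); off by default. The summary reports
    the count, mean, and SD of the flagged finite ratios; focal-exclusive
    clusters (f_ocean = 0, f_so > 0) are flagged and counted separately but
    excluded from the mean/SD.
    """
    f = frequencies.copy()
    f = f[f["n_members_total"] >= min_size].reset_index(drop=True)
    f_so = f["f_so"].to_numpy(dtype=float)
    f_ocean = f["f_ocean"].to_numpy(dtype=float)
    if pseudo_count:
        if not n_so_pool or not n_ocean_pool:
            raise ValueError("pseudo_count requires n_so_pool and n_ocean_pool")
        ratio = ((f_so * n_so_pool + 1) / (n_so_pool + 1)) / (
            (f_ocean * n_ocean_pool + 1) / (n_ocean_pool + 1)
        )
        exclusive = np.zeros_like(ratio, dtype=bool)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(f_ocean > 0, f_so / np.where(f_ocean > 0, f_ocean, 1.0), np.nan)
        exclusive = (f_ocean == 0) & (f_so > 0)
    flagged = np.where(np.isnan(ratio), False, ratio >= ratio_threshold)
    f["ratio"] = ratio
    f["overrepresented"] = flagged
    f["so_exclusive"] = exclusive
    finite_flagged = f.loc[f["overrepresented"], "ratio"].to_numpy(dtype=float)
    summary = EnrichmentSummary(
        n_clusters_tested=len(f),
        n_overrepresented=int(flagged.sum()),
        n_so_exclusive=int(exclusive.sum()),
        mean_ratio=float(finite_flagged.mean()) if finite_flagged.size else float("nan"),
        sd_ratio=float(finite_flagged.std(ddof=1)) if finite_flagged.size > 1 else float("nan"),
    )
    return f, summary
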