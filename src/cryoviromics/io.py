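"""Readers and writers for the four standard inputs and all tabular outputs.

Fixed dialect everywhere: TSV with a header row, tab delimiter, UTF-8, "."
decimal separator, so every output is diffable. FASTA goes through biopython.

Record sanitization policy: amino-acid sequences are restricted to the 20
canonical one-letter codes; anything else (B, J, O, U, X, Z, ``*``, gaps) is
dropped with a logged count rather than raised, because environmental gene
predictions routinely contain ambiguity codes and internal stops. Records
emptied by sanitization are skipped with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cryoviromics")

#: Canonical amino-acid alphabet, alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = frozenset(AA_ALPHABET)

COVERAGE_COLUMNS = ["genome_id", "sample_id", "genome_length", "breadth_1x", "read_count"]


class ValidationError(ValueError):
    """Raised when an input file or configuration violates its contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein with its oceanic-region label."""

    id: str
    region: str
    sequence: str


@dataclass(frozen=True)
class ClusterMembership:
    """A protein cluster and the (genome, region) pairs carrying it."""

    cluster_id: str
    members: frozenset  # of (genome_id, region) tuples


# -- region resolution -------------------------------------------------------

def _region_lookup(metadata: Mapping[str, str] | pd.DataFrame) -> Mapping[str, str]:
    if isinstance(metadata, pd.DataFrame):
        if not {"sample_id", "region"} <= set(metadata.columns):
            raise ValidationError("metadata table needs 'sample_id' and 'region' columns")
        return dict(zip(metadata["sample_id"], metadata["region"]))
    return dict(metadata)


def resolve_region(record_id: str, lookup: Mapping[str, str]) -> str:
    """Region for a record id: exact match first, then the prefix before '|'."""
    if record_id in lookup:
        return lookup[record_id]
    prefix = record_id.split("|", 1)[0]
    if prefix in lookup:
        return lookup[prefix]
    raise ValidationError(f"no region label resolvable for record {record_id!r}")


# -- protein FASTA -----------------------------------------------------------

def sanitize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase and drop non-canonical characters; return (clean, n_dropped)."""
    upper = raw.upper()
    clean = "".join(c for c in upper if c in _CANONICAL)
    return clean, len(upper) - len(clean)


def read_protein_fasta(
    path: str | Path,
    metadata: Mapping[str, str] | pd.DataFrame,
) -> list[ProteinRecord]:
    """Read an amino-acid FASTA into sanitized, region-labelled records.

    ``metadata`` maps record ids (or their prefix before the first ``|``)
    to region labels; a sample-metadata DataFrame with ``sample_id`` and
    ``region`` columns is also accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lookup = _region_lookup(metadata)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    dropped_total = 0
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        clean, dropped = sanitize_sequence(str(rec.seq))
        dropped_total += dropped
        if not clean:
            skipped += 1
            logger.warning("record %s emptied by sanitization; skipped", rec.id)
            continue
        if rec.id in seen:
            raise ValidationError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, region=resolve_region(rec.id, lookup), sequence=clean))
    if dropped_total:
        logger.info("sanitization dropped %d non-canonical characters from %s", dropped_total, path)
    if not records:
        logger.warning("no usable protein records in %s (skipped %d)", path, skipped)
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def write_nucleotide_fasta(genomes: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (genome_id, sequence) pairs as nucleotide FASTA."""
    seqs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in genomes]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def read_nucleotide_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# -- coverage table ----------------------------------------------------------

def validate_coverage(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"coverage table missing columns: {missing}")
    df = df[COVERAGE_COLUMNS].copy()
    try:
        df["genome_length"] = pd.to_numeric(df["genome_length"], downcast=None).astype("int64")
        df["read_count"] = pd.to_numeric(df["read_count"]).astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-integer genome_length or read_count: {exc}") from exc
    df["breadth_1x"] = pd.to_numeric(df["breadth_1x"]).astype(float)
    if (df["genome_length"] <= 0).any():
        raise ValidationError("genome_length must be positive")
    if (df["read_count"] < 0).any():
        raise ValidationError("read_count must be non-negative")
    bad = df[(df["breadth_1x"] < 0) | (df["breadth_1x"] > 1)]
    if len(bad):
        raise ValidationError(
            f"breadth_1x outside [0, 1] for {bad.iloc[0]['genome_id']}/{bad.iloc[0]['sample_id']}"
        )
    zero = df[(df["read_count"] == 0) & (df["breadth_1x"] > 0)]
    if len(zero):
        raise ValidationError(
            "read_count = 0 with breadth_1x > 0 for "
            f"{zero.iloc[0]['genome_id']}/{zero.iloc[0]['sample_id']}"
        )
    dup = df.duplicated(subset=["genome_id", "sample_id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["genome_id", "sample_id"]]
        raise ValidationError(f"duplicate coverage rows for ({pair.genome_id}, {pair.sample_id})")
    return df


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read per-genome-per-sample coverage summaries (typed and validated)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_coverage(pd.read_csv(path, sep="\t"))


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_coverage(df).to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- cluster membership ------------------------------------------------------

def read_cluster_table(
    path: str | Path,
    genome_regions: Mapping[str, str],
) -> list[ClusterMembership]:
    """Read a (cluster_id, genome_id) TSV into per-cluster memberships.

    Duplicate rows are deduplicated with a log line; genomes missing from
    ``genome_regions`` are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cluster_id", "genome_id"} <= set(df.columns):
        raise ValidationError("cluster table needs 'cluster_id' and 'genome_id' columns")
    n_dup = int(df.duplicated().sum())
    if n_dup:
        logger.info("deduplicated %d repeated (cluster, genome) rows in %s", n_dup, path)
        df = df.drop_duplicates()
    unmapped = sorted(set(df["genome_id"]) - set(genome_regions))
    if unmapped:
        raise ValidationError(f"genomes without a region label: {unmapped[:5]}")
    memberships = []
    for cluster_id, sub in df.groupby("cluster_id", sort=True):
        members = frozenset((g, genome_regions[g]) for g in sub["genome_id"])
        memberships.append(ClusterMembership(cluster_id=str(cluster_id), members=members))
    return memberships


def write_cluster_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows[["cluster_id", "genome_id"]].to_csv(path, sep="\t", index=False)


# -- sample metadata ---------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "region"} <= set(df.columns):
        raise ValidationError("sample metadata needs 'sample_id' and 'region' columns")
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- generic tables and the run manifest ------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any tabular output in the fixed TSV dialect."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    config: Mapping,
    seed: int | None,
    files: Sequence[str | Path],
) -> Path:
    """Record config, seed, and a checksum per declared output file (JSON)."""
    outdir = Path(outdir)
    manifest = {
        "config": dict(config),
        "seed": seed,
        "files": {
            str(Path(f).relative_to(outdir)): sha256_file(f)
            for f in sorted(map(Path, files))
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
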