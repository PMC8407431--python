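"""End-to-end orchestration: synthetic or user inputs through every stage.

Stage order: io -> community ecology -> k-mer profiles -> protein
properties -> effect statistics -> cluster enrichment. Every output is a
TSV in the fixed dialect plus one ``manifest.json`` recording the config,
the seed, and a checksum per declared file; nothing is written outside the
manifest. The whole run is deterministic under a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import community, enrichment, kmers, properties, stats, synthetic
from .io import (
    ValidationError,
    read_cluster_table,
    read_coverage_table,
    read_nucleotide_fasta,
    read_protein_fasta,
    read_sample_metadata,
    write_cluster_table,
    write_coverage_table,
    write_manifest,
    write_nucleotide_fasta,
    write_protein_fasta,
    write_sample_metadata,
    write_table,
)

logger = logging.getLogger("cryoviromics")

ALL_STAGES = ("community", "kmer", "properties", "stats", "enrich")


@dataclass
class RunConfig:
    """One run's full parameterization; round-trips through JSON."""

    output_dir: str
    seed: int = 0
    # either a synthetic scenario ...
    use_synthetic: bool = True
    n_proteins_per_region: int = 2000
    n_genomes_per_region: int = 100
    n_samples_per_region: int = 4
    genome_length: int = 10_000
    other_regions: Sequence[str] = ("SATL",)
    # ... or user-supplied inputs
    protein_fasta: str | None = None
    genome_fasta: str | None = None
    coverage_table: str | None = None
    cluster_table: str | None = None
    sample_metadata: str | None = None
    genome_region_table: str | None = None
    # thresholds
    so_label: str = "SO"
    breadth_threshold: float = 0.75
    css_quantile: float = 0.5
    abundance_filter: float = 0.01
    min_cluster_size: int = 50
    ratio_threshold: float = 5.0
    alpha: float = 0.01
    correction: str = "holm"
    mantel_permutations: int = 999
    stages: Sequence[str] = ALL_STAGES

    def validate(self) -> "RunConfig":
        if not 0 <= self.breadth_threshold <= 1:
            raise ValidationError("breadth_threshold must be in [0, 1]")
        if not 0 < self.css_quantile <= 1:
            raise ValidationError("css_quantile must be in (0, 1]")
        if not 0 <= self.abundance_filter < 1:
            raise ValidationError("abundance_filter must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_cluster_size < 1 or self.ratio_threshold <= 0:
            raise ValidationError("min_cluster_size and ratio_threshold must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["other_regions"] = list(self.other_regions)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _stage_log(stage: str, **counts) -> None:
    fields = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, fields)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        write_table(df, path, index=index)
        written.append(path)

    # ----- inputs -------------------------------------------------------
    if config.use_synthetic:
        scenario = synthetic.default_scenario(
            seed=config.seed,
            so_label=config.so_label,
            other_regions=tuple(config.other_regions),
            n_proteins_per_region=config.n_proteins_per_region,
            n_genomes_per_region=config.n_genomes_per_region,
            n_samples_per_region=config.n_samples_per_region,
            genome_length=config.genome_length,
        )
        bundle = synthetic.generate_all(scenario)
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        write_protein_fasta(bundle.proteins, inputs / "proteins.faa")
        write_nucleotide_fasta(bundle.genomes, inputs / "genomes.fna")
        write_coverage_table(bundle.coverage, inputs / "coverage.tsv")
        write_cluster_table(bundle.membership, inputs / "clusters.tsv")
        write_sample_metadata(bundle.metadata, inputs / "sample_metadata.tsv")
        written += sorted(inputs.iterdir())
        truths = outdir / "truth"
        truths.mkdir(exist_ok=True)
        write_table(bundle.proteome_truth, truths / "proteome_truth.tsv")
        write_table(bundle.coverage_truth, truths / "coverage_truth.tsv")
        write_table(bundle.membership_truth, truths / "membership_truth.tsv")
        written += sorted(truths.iterdir())
        proteins = bundle.proteins
        genomes = dict(bundle.genomes)
        coverage = bundle.coverage
        membership = bundle.membership
        metadata = bundle.metadata
        genome_regions = bundle.genome_regions
    else:
        metadata = read_sample_metadata(config.sample_metadata) if config.sample_metadata else None
        proteins = (
            read_protein_fasta(config.protein_fasta, metadata)
            if config.protein_fasta
            else None
        )
        coverage = read_coverage_table(config.coverage_table) if config.coverage_table else None
        genomes = dict(read_nucleotide_fasta(config.genome_fasta)) if config.genome_fasta else None
        genome_regions = None
        if config.genome_region_table:
            grt = pd.read_csv(config.genome_region_table, sep="\t")
            genome_regions = dict(zip(grt["genome_id"], grt["region"]))
        membership = None
        if config.cluster_table:
            if genome_regions is None:
                raise ValidationError("cluster_table requires genome_region_table")
            pairs = [
                {"cluster_id": m.cluster_id, "genome_id": g}
                for m in read_cluster_table(config.cluster_table, genome_regions)
                for g, _ in sorted(m.members)
            ]
            membership = pd.DataFrame(pairs)

    sample_regions = (
        dict(zip(metadata["sample_id"], metadata["region"])) if metadata is not None else {}
    )

    # ----- community ecology -------------------------------------------
    presence = None
    if "community" in config.stages:
        if coverage is None:
            raise ValidationError("community stage requires a coverage table")
        presence = community.apply_presence_rule(coverage, config.breadth_threshold)
        lengths = coverage.drop_duplicates("genome_id").set_index("genome_id")["genome_length"]
        normalized = community.length_library_normalize(presence, lengths)
        css = community.css_normalize(normalized, quantile=config.css_quantile)
        emit(css, "community_abundance_css.tsv", index=True)
        emit(community.diversity_table(css), "community_diversity.tsv")
        bc = community.bray_curtis(css)
        emit(bc, "community_bray_curtis.tsv", index=True)
        _, labels, newick = community.hierarchical_cluster(bc)
        (outdir / "community_dendrogram.nwk").write_text(newick + "\n")
        written.append(outdir / "community_dendrogram.nwk")
        display = community.filter_relative_abundance(css, config.abundance_filter)
        emit(display, "community_abundant_members.tsv", index=True)
        if metadata is not None and "temperature" in metadata.columns:
            env = community.environment_distance(metadata, ["temperature"])
            result = community.mantel(
                bc, env, n_permutations=config.mantel_permutations, seed=config.seed
            )
            emit(
                pd.DataFrame(
                    [
                        {
                            "variable": "temperature",
                            "mantel_r": result.r,
                            "p_value": result.p,
                            "n_permutations": result.n_permutations,
                        }
                    ]
                ),
                "community_mantel.tsv",
            )
        _stage_log("community", genomes=presence.shape[0], samples=presence.shape[1])

    # ----- k-mer profiles ----------------------------------------------
    if "kmer" in config.stages:
        if genomes is None or coverage is None:
            raise ValidationError("kmer stage requires genomes and coverage")
        if presence is None:
            presence = community.apply_presence_rule(coverage, config.breadth_threshold)
        profiles = []
        for sample in presence.columns:
            members = presence.index[presence[sample] > 0]
            seqs = [genomes[g] for g in members if g in genomes]
            if not seqs:
                logger.warning("sample %s has no present genomes; skipped in k-mer stage", sample)
                continue
            profiles.append(kmers.tetranucleotide_profile(seqs, sample_id=sample))
        frame = kmers.profiles_to_frame(profiles)
        emit(frame, "kmer_profiles.tsv", index=True)
        kd = kmers.profile_distance_matrix(frame)
        emit(kd, "kmer_bray_curtis.tsv", index=True)
        coords, explained = kmers.pca_ordination(frame)
        coords = coords.copy()
        coords.insert(0, "sample_id", coords.index)
        coords["region"] = [sample_regions.get(s, "") for s in coords["sample_id"]]
        emit(coords, "kmer_ordination.tsv")
        emit(
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(explained))],
                          "explained_fraction": explained}),
            "kmer_explained_variance.tsv",
        )
        _stage_log("kmer", samples=len(profiles))

    # ----- protein properties ------------------------------------------
    props = None
    if "properties" in config.stages or "stats" in config.stages:
        if proteins is None:
            raise ValidationError("properties stage requires a protein FASTA")
        props = properties.summarize_proteome(proteins)
    if "properties" in config.stages:
        emit(props, "protein_properties.tsv")
        emit(properties.region_summary(props), "protein_region_summary.tsv")
        emit(properties.lysine_arginine_ratio(props), "protein_k_to_r_ratio.tsv")
        _stage_log("properties", proteins=len(props))

    # ----- effect statistics --------------------------------------------
    if "stats" in config.stages:
        value_cols = ["hy", "mw", "pi"] + [f"freq_{aa}" for aa in "PRKNMY"]
        effects = stats.effect_size_table(props, value_cols, reference=config.so_label)
        emit(effects, "effect_sizes.tsv")
        comparisons = stats.group_comparison_table(
            props, value_cols, alpha=config.alpha, correction=config.correction
        )
        emit(comparisons, "group_comparisons.tsv")
        averages = pd.DataFrame(
            [
                {
                    "property": col,
                    "average_abs_d": stats.average_abs_d(effects, col),
                    "cl_of_average": stats.common_language_effect(
                        stats.average_abs_d(effects, col)
                    ),
                }
                for col in value_cols
            ]
        )
        emit(averages, "effect_size_averages.tsv")
        _stage_log("stats", properties=len(value_cols))

    # ----- cluster enrichment -------------------------------------------
    if "enrich" in config.stages:
        if membership is None or genome_regions is None:
            raise ValidationError("enrich stage requires cluster membership and genome regions")
        freqs = enrichment.cluster_frequencies(membership, genome_regions, so_label=config.so_label)
        table, summary = enrichment.overrepresented_clusters(
            freqs, min_size=config.min_cluster_size, ratio_threshold=config.ratio_threshold
        )
        emit(table, "cluster_enrichment.tsv")
        emit(pd.DataFrame([dataclasses.asdict(summary)]), "cluster_enrichment_summary.tsv")
        _stage_log("enrich", clusters=summary.n_clusters_tested, flagged=summary.n_overrepresented)

    (outdir / "config.json").write_text(config.to_json() + "\n")
    written.append(outdir / "config.json")
    write_manifest(outdir, json.loads(config.to_json()), config.seed, written)
    return outdir


def make_demo(seed: int = 0, output_dir: str | Path = "demo_out") -> Path:
    """Small single-command demonstration: a two-region scenario (4 samples
    per region, 2,000 proteins per region, 200 genomes) and its complete
    analysis."""
    config = RunConfig(output_dir=str(output_dir), seed=seed)
    return run_pipeline(config)
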