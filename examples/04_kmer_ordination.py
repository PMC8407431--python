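"""Reference-free comparison by canonical tetranucleotide signatures.

Profiles each sample's genome pool into 136 strand-collapsed 4-mer
classes, computes Bray-Curtis distances and a principal-coordinates
ordination; the GC-biased cold-region samples separate on the first axis.
"""

from cryoviromics import community, kmers, synthetic

scenario = synthetic.default_scenario(
    seed=9, n_genomes_per_region=40, n_samples_per_region=3, genome_length=5000
)
genomes, coverage, _ = synthetic.generate_genomes_and_coverage(scenario)
genome_seqs = dict(genomes)

presence = community.apply_presence_rule(coverage)
profiles = []
for sample in presence.columns:
    members = presence.index[presence[sample] > 0]
    profiles.append(
        kmers.tetranucleotide_profile([genome_seqs[g] for g in members], sample_id=sample)
    )

coords, explained = kmers.pca_ordination(profiles, n_components=2)
print("principal-coordinate ordination of tetranucleotide profiles:")
print(coords.round(4).to_string())
print(f"\nexplained variance: PC1 {100 * explained[0]:.1f}%, PC2 {100 * explained[1]:.1f}%")
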