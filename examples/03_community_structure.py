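"""From coverage summaries to community structure.

Applies the breadth-of-coverage presence rule (>= 1x depth across >= 75%
of the genome), normalizes by genome length / library size and by
cumulative-sum scaling, then prints diversity indices, the Bray-Curtis
dissimilarities, and the temperature Mantel test.
"""

from cryoviromics import community, synthetic

scenario = synthetic.default_scenario(
    seed=4, n_genomes_per_region=80, n_samples_per_region=3, genome_length=5000
)
_, coverage, truth = synthetic.generate_genomes_and_coverage(scenario)
metadata = synthetic.generate_sample_metadata(scenario)

presence = community.apply_presence_rule(coverage, breadth_threshold=0.75)
lengths = coverage.drop_duplicates("genome_id").set_index("genome_id")["genome_length"]
normalized = community.length_library_normalize(presence, lengths)
css = community.css_normalize(normalized)

print("per-sample diversity (richness, Shannon H' in nats, Pielou J):")
print(community.diversity_table(css).to_string(index=False))

bc = community.bray_curtis(css)
print("\nmean Bray-Curtis within SO samples:",
      round(bc.filter(like="SO", axis=0).filter(like="SO", axis=1).values.mean(), 3))
print("mean Bray-Curtis SO vs other:",
      round(bc.filter(like="SO", axis=0).filter(like="SATL", axis=1).values.mean(), 3))

env = community.environment_distance(metadata, ["temperature"])
result = community.mantel(bc, env, n_permutations=999, seed=4)
print(f"\nMantel r = {result.r:.2f}, p = {result.p:.3f} "
      "(community distance vs temperature distance)")
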