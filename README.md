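# cryoviromics

Comparative viromics of cold-ocean communities: a Python library for asking
how the viral community of an isolated, near-freezing oceanic region differs
from warm-ocean communities — in composition, in genomic signature, in gene
content, and in the physical chemistry of its predicted proteome.

The package is aimed at viral ecologists who already have the standard
upstream products in hand (predicted proteins, assembled viral genomes,
read-mapping coverage summaries, and a gene-sharing protein-cluster table)
and want a tested, reproducible implementation of the comparative analysis
itself. A seeded synthetic-data generator emulates all four inputs with
planted ground truth, so every stage can be validated end to end without
touching real data.

## What it computes

**Community structure.** A genome counts as present in a sample only with
≥ 1× read depth across ≥ 75% of its length (breadth-of-coverage presence
rule); retained counts are normalized by genome length and library size and
then by cumulative-sum scaling (CSS). On the resulting abundance matrix:
Shannon–Wiener H′ (nats) and Pielou evenness J = H′/ln S, Bray–Curtis
dissimilarity BC(u, v) = 1 − 2Σmin(uᵢ, vᵢ)/(Σu + Σv), average-linkage
hierarchical clustering (Newick export), a seeded Mantel permutation test
against environmental distance, and the >1% relative-abundance display
filter.

**Genomic signatures.** Canonical (strand-collapsed) tetranucleotide
profiles — 136 classes: 16 palindromes plus 120 reverse-complement pairs —
compared by Bray–Curtis and ordinated by principal coordinates.

**Gene-content enrichment.** Carriage frequency f of a protein cluster in a
genome pool is the fraction of genomes encoding at least one member.
Clusters carried by ≥ 50 genomes whose focal-region frequency is ≥ 5× the
pooled frequency of all other regions are flagged as overrepresented;
focal-exclusive clusters (f_other = 0) are reported separately.

**Proteome physicochemistry.** Per protein: amino-acid composition, GRAVY
hydropathy (mean Kyte–Doolittle value, range ±4.5), average molecular
weight, and the isoelectric point (bisection on the Henderson–Hasselbalch
net-charge curve, EMBOSS pKa set by default). Regions are compared with
Kruskal–Wallis, pairwise Wilcoxon rank-sum with Holm correction and compact
letter display, and Cohen's d

    d = (mean_other − mean_focal) / pooled SD,

read out as the common-language effect size (probability of superiority)
Φ(d/√2) — the chance that a random protein from one group exceeds a random
protein from the other.

## Worked example

```bash
python examples/02_effect_sizes.py
```

```
effect sizes, sign convention (other region - SO):
  hy      d = +0.072  P(superiority) = 52.0%
  freq_P  d = +0.972  P(superiority) = 75.4%
  freq_K  d = -0.878  P(superiority) = 26.7%

Phi(0.45/sqrt(2)) = 62.5%

Phi(0.32/sqrt(2)) = 59.0%

Kruskal-Wallis + Wilcoxon letters for GRAVY:
property  kw_statistic     kw_p letters_SATL letters_SO
      hy      7.377148 0.006606            a          b
```

The synthetic cold region ("SO") was generated with lower proline and
arginine and higher lysine frequencies, so the d signs recover the planted
directions: positive d for hydropathy and proline (the cold region is lower
on both), negative for lysine (higher in the cold region). The distinct
Wilcoxon letters (a vs b) say the two regional GRAVY distributions differ
at α = 0.01. The closed-form conversions show how an average d of 0.45
reads as a 62.5% probability of superiority, and d = 0.32 as 59%.

The other examples cover protein indices and the K:R ratio (`01`),
community diversity and the Mantel test (`03`), tetranucleotide ordination
(`04`), and cluster enrichment (`05`). A complete run over synthetic inputs
in one command:

```bash
cryoviromics demo --seed 1 --out demo_out
```

which writes every stage's TSV outputs, the generated inputs and their
truth tables, and a `manifest.json` with the config, seed, and per-file
checksums (byte-identical across reruns with the same seed).

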