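# Methods

This note documents the models, parameter choices, and numerical decisions
behind cryoviromics, and what the synthetic-data validation does and does
not demonstrate about real data.

## The comparison being modeled

The library addresses a recurring design in marine viral ecology: one
focal oceanic region under strong, distinctive selection (here, a polar
region near the freezing point of seawater) is compared against a pooled
set of warm reference regions on four axes — community composition,
genome-wide k-mer signature, gene content, and bulk proteome
physicochemistry. All inputs are the standard products of a viromics
workflow (predicted proteins, assembled genomes, mapping coverage
summaries, gene-sharing cluster tables); the library implements the
comparative analysis, not the upstream assembly, gene calling, mapping, or
clustering.

## Community matrix

**Presence rule.** A genome is present in a sample only when mapped reads
give ≥ 1× depth across at least 75% of its positions (breadth of
coverage); otherwise its count is zeroed. The boundary is inclusive
(exactly 75% passes) because the rule is phrased as a minimum. Breadth
filtering guards against spurious abundances from reads that pile onto a
conserved gene of an absent genome.

**Normalization.** Retained counts are divided by genome length (per kb)
and then by the sample's retained-read total (per million); cumulative-sum
scaling follows, with a per-sample factor equal to the sum of counts at or
below the q-th quantile of the sample's non-zero counts (q = 0.5 by
default, configurable), times a fixed 1,000. CSS damps the influence of a
few highly dominant genomes on between-sample distances. The stage order —
presence rule, then length/library, then CSS — is fixed and recorded in
each matrix's stage tag. We deliberately use a fixed quantile rather than
an adaptively chosen one: the adaptive instability criterion adds a data
dependence that is hard to reproduce, and at these community sizes the
fixed median behaves equivalently.

**Diversity and distance.** Shannon H′ uses natural logarithms (nats; the
base is an argument), so Pielou J = H′/ln S lands in [0, 1]. Bray–Curtis
is computed on normalized columns. Hierarchical clustering is
average-linkage over the lexicographically sorted samples, which makes tie
breaking deterministic; the dendrogram is exported as Newick with branch
lengths taken as differences of merge heights.

**Mantel test.** Pearson correlation of lower-triangle distances, with a
one-sided permutation p-value (1 + #{r_perm ≥ r_obs})/(1 + n_perm),
permuting one matrix's rows and columns jointly under a caller-supplied
seed. Environmental distance is Euclidean on z-scored variables — the
simplest defensible construction when only scalar covariates (e.g.
temperature) are available.

## Tetranucleotide profiles

Profiles slide a k = 4 window with step 1; windows containing anything
outside ACGT contribute nothing (the window restarts past the offending
character). Each 4-mer is pooled with its reverse complement into the
lexicographically smaller of the pair, because read and contig orientation
is arbitrary; this yields 136 classes. Ordination is principal coordinates
on the Bray–Curtis matrix (Gower double centering of −D²/2,
eigendecomposition, coordinates scaled by √eigenvalue), with signs fixed
by making each component's largest-magnitude loading positive so reruns
are comparable. A raw-frequency PCA mode exists for exploration.

## Cluster enrichment

Carriage is binary per genome (multiple member proteins count once).
Frequencies are taken over all genomes of each pool by default; a
`clustered_only` switch restricts denominators to genomes that appear in
at least one cluster, since published analyses are ambiguous on this
point. The size filter (≥ 50 carrying genomes across both pools, applied
before ratio evaluation) excludes rare clusters whose frequency ratios are
dominated by sampling noise. Clusters absent from the reference pool have
no finite ratio; reporting them as focal-exclusive rather than infinite
keeps the flagged-ratio mean/SD meaningful. An optional add-one
pseudo-count mode is available but off by default.

## Protein indices

* **Composition** is counts over length, in fixed alphabetical one-letter
  order (ACDEFGHIKLMNPQRSTVWY).
* **GRAVY** is the arithmetic mean of Kyte–Doolittle values — the de facto
  standard hydropathy scale, spanning −4.5 (Arg) to +4.5 (Ile). Reported
  per residue, not summed: bulk means near −0.4 on this scale only make
  sense as per-residue averages.
* **Molecular weight** sums average (isotope-abundance weighted) residue
  masses plus one water (18.0153 Da). Average rather than monoisotopic
  masses match bulk-property reporting.
* **Isoelectric point** models net charge by Henderson–Hasselbalch over
  the two termini and the D, E, C, Y, H, K, R side chains, then bisects
  [0, 14] to an interval below 1e−4 pH. We bisect on the interval rather
  than stopping at a small |charge| because weakly buffered compositions
  (e.g. peptides with no ionizable side chains) have nearly flat charge
  curves near the root, where a charge criterion stops early. The pKa set
  is the EMBOSS default and is an explicit, swappable parameter — pI tools
  differ in their sets, so absolute pI values are comparable only within
  one set. Cysteines are treated as free thiols; disulfide state is not
  inferable from sequence.
* **Sanitization**: non-canonical residues (B, J, O, U, X, Z, stops,
  gaps) are dropped with a logged count rather than raised — environmental
  gene predictions routinely contain them, and dropping preserves the
  composition of known residues. The half-life descriptor sometimes seen
  in bulk property tables is out of scope (no defined algorithm).

## Effect statistics

Cohen's d uses the pooled (Bessel-corrected, df-weighted) SD. The sign
convention is (other region − focal region), so positive d for hydropathy
means the focal proteome is less hydrophobic. The common-language effect
size Φ(d/√2) is the normal-theory probability that a random draw from the
higher-mean group exceeds one from the other; "average Cohen's d" for a
property is the unweighted mean of |d| across the region-versus-focal
pairs. Rank tests: Kruskal–Wallis with tie correction; pairwise Wilcoxon
rank-sum, exact by enumeration when both groups are ≤ 20 and tie-free,
otherwise the tie- and continuity-corrected normal approximation. Pairwise
p-values are Holm-adjusted by default ("none" mirrors analyses that report
raw p); α defaults to 0.01. Letter groups come from the insert-and-absorb
algorithm with deterministic ordering, so regions sharing no letter differ
significantly at α.

## Synthetic data: what is planted and why

The generator's defaults are the package's reference study conditions.

* **Baseline composition** is the Swiss-Prot-style average amino-acid
  frequency vector. The cold region applies additive shifts in the six
  canonical cold-adaptation directions — proline and arginine down;
  lysine, asparagine, methionine, tyrosine up — with magnitudes chosen so
  the shifted residues land on frequencies reported for cold-ocean viral
  proteomes (P 0.03, R 0.04, K 0.08, N 0.05, M 0.03, Y 0.04). These
  shifts lower mean Kyte–Doolittle hydropathy and raise the K:R ratio, so
  every downstream sign check is a genuine construction, not a tuned one.
* **Protein lengths** are log-normal (meanlog 5.1, sdlog 0.85), rounded,
  clamped at 30 aa — reproducing the heavy-tailed ~25 kDa mean / ~28 kDa
  SD molecular-weight scale of real viral proteomes. Residues are i.i.d.
  within a protein: all assayed statistics are composition-level, so
  positional structure would add cost without changing any tested
  quantity.
* **Planted GRAVY effects.** For a target standardized difference d*, the
  cold profile is produced by exponential tilting along the hydropathy
  scale, pᵢ ∝ bᵢ·e^(−τ·kdᵢ), with τ solved against the closed-form
  moments: per-protein GRAVY has mean p·kd and variance Var_kd(p)·E[1/L],
  with E[1/L] integrated over the discrete length model. Tilting is used
  because the six-residue cold direction saturates (its maximum feasible
  magnitude yields d ≈ 0.27) while the tilt can reach any d* smoothly and
  keeps all frequencies positive. The planted d* = 0.45 recovery band of
  [0.40, 0.50] at 10,000 proteins/group corresponds to ±3.5 standard
  errors of d̂.
* **Genomes** come from a first-order chain over tetranucleotide weights
  (default: factorized weights from a per-region GC fraction, 0.43 cold
  vs 0.52 warm — matching the modest GC contrast of real data while
  giving k-mer ordination a recoverable signal).
* **Coverage** draws intended presence per genome × sample (probability
  0.9 in the home region, 0.25 away), breadth uniform on [0.80, 1.0] for
  present pairs and [0, 0.70] for absent ones — straddling the 75% rule
  with a margin, so the truth table's intended-presence column is exactly
  recoverable. Read counts are Poisson around depth × length/read-length
  with log-normal per-genome abundance (giving realistic unevenness);
  a zero draw forces breadth 0 to respect the coverage invariant.
* **Cluster carriage** is independent Bernoulli per genome at per-pool
  target frequencies. The default scenario plants ten 6× clusters
  (f_focal 0.6, f_other 0.1) over a ratio-1 background. Recovery with
  precision = recall = 1 is asserted at pool sizes (500/5,000) where the
  binomial SE of the realized ratio is several times smaller than the
  distance to the 5× boundary; at small demo pools the realized ratio can
  legitimately cross the boundary, which is why truth tables record
  realized (not just target) frequencies.
* **Sample metadata** carries a temperature covariate (≈0.5 °C cold
  region, ≈18 °C elsewhere, SD 1) for the Mantel stage.

**What passing tests do not show.** The generator has no phylogenetic or
positional structure, no sequencing error, no assembly artifacts, no
correlated cluster carriage, and i.i.d. residues; recovery on it validates
the statistical machinery and its thresholds, not the upstream
bioinformatics, and says nothing about whether real regional differences
exist — only that if they exist at the planted magnitudes, this pipeline
measures them correctly.

## Problem sizes and determinism

Default analyses run at desk scale: the demo uses 2 regions × 4 samples,
2,000 proteins and 100 genomes per region (about 4 s end to end); the
recovery suites use up to 10,000 proteins per group × 100 seeds and
500/5,000-genome pools. Every random draw flows from
`numpy.random.default_rng` seeded by the scenario or config seed (each
generator on its own seed stream), so reruns are byte-identical, as the
manifest checksums assert.

## Known limitations

* NMDS and ANOSIM are not provided; ordination is principal coordinates
  and the environmental association is the Mantel test.
* CSS uses a fixed quantile, not the adaptive criterion of the original
  normalization package.
* The ">1% across all samples" display filter is implemented as "exceeds
  1% in at least one sample"; a per-sample-mean reading is the plausible
  alternative and is trivially expressible on the returned matrix.
* pI values depend on the chosen pKa set and ignore disulfides and
  post-translational chemistry.
* The Wilcoxon exact path requires tie-free groups; with ties it falls
  back to the corrected normal approximation even for small n.
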