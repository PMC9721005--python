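# Methods

## Species delineation from marker genes

The unit of analysis is a genome's complement of ten universal, single-copy,
protein-coding marker-gene (MG) families (labelled COG0012, COG0016,
COG0018, COG0172, COG0215, COG0495, COG0525, COG0533, COG0541, COG0552).
Two genomes belong to the same species-level unit (mOTU) when the mean of
their per-family global-alignment identities reaches the species boundary.

**Identity definition.** Identity = matches / alignment columns of a global
(Needleman–Wunsch) alignment, columns including internal gaps. With unit
edit costs this equals 1 − edit_distance / columns, which is what the edlib
backend computes. This definition is pinned because every threshold in the
package (species boundary, prefilter, report floor) is interpreted against
it. Reverse complements are always tried; the better strand wins.

**Cutoffs.** The per-family identity cutoff defaults to a uniform 96.5% —
the published species-level boundary for marker-gene identity — and is
loadable per family from the database's `cutoffs.tsv`. The candidate
prefilter is 80% identity, mirroring the database-mapping step of the
original pipeline. Where a rule needs a single number for a set of families
(de novo clustering on shared families), the mean of the per-family cutoffs
is used; under the uniform default this is exactly 96.5%.

## Database construction and extension

`extend_database` gives every input genome exactly one fate:

1. **rejected** — fewer than `min_families` (default 6) of the 10 families;
2. **assigned** — at least `min_assign_families` (default 3) families have a
   best hit meeting their family cutoff against some existing mOTU; the
   mOTU with the highest mean per-family best-hit identity wins, ties
   breaking to the lexicographically smaller id. Assigned genomes are
   recorded as members but their sequences are *not* added — they are
   already represented;
3. **new ext-mOTU member** — the remainder is clustered de novo.

De novo clustering is greedy centroid clustering: genomes sorted by family
count (descending), then genome id; each joins the first centroid whose
mean MG identity over shared families reaches the cutoff, else founds a new
cluster. The original pipeline's de novo rule is not published in detail;
greedy centroid (vsearch-`cluster_fast`-like) with a deterministic input
order was chosen for reproducibility and is the main place this
reimplementation could deviate from the original tool's groupings.
Extension is idempotent: re-extending with the same genomes assigns all of
them and creates nothing.

`min_assign_families = 3` is a package choice: the original tool's quorum
is unpublished; three families balance sparse MG complements (six-family
genomes) against false merging on a single aberrant gene.

The single pooled **unassigned** entry holds MG representatives that belong
to no mOTU. `update_unassigned` clusters leftover MGs per family at the
family cutoff, seeding centroids with the existing representatives (so
duplicates add nothing) and keeping the longest member of each new cluster.

Consensus taxonomy (`annotate_consensus`): at each rank the name carried by
more than half of the annotated marker genes wins (categories: `agreeing`
unanimous, `majority` >50%, `not_agreeing` no majority → rank unannotated,
`not_annotated` nothing annotated); once a rank is unannotated all lower
ranks are truncated.

## Profiling model

Inserts (one count per sequenced fragment; a read pair contributes one
insert whose evidence is the better mate) are aligned to all database MGs
via a k-mer seed index (k = 14, both strands) and semi-global (edlib "HW")
verification. Hits require identity ≥ 0.93 (report floor) and ≥ 45 aligned
bases — the floor and length mirror the mapping filters of the original
read-processing pipeline; the insert-resolution rule itself is this
package's explicit stand-in for the original profiler's unpublished
internals. The best hit per insert (identity, then aligned length, then
lexicographic id) decides:

- identity ≥ family cutoff → that mOTU (hits on unassigned-entry sequences
  count as unassigned);
- floor ≤ identity < cutoff → the unassigned pool;
- no hits → discarded.

**Quantification.** Counts mode reports integer inserts per mOTU. Relative
abundance mode scores each mOTU as the mean over its families of
(inserts assigned to the family) / (total family sequence length in kb),
then normalizes all scores — including the unassigned pool — to sum to 1.
Because inserts are sampled proportionally to abundance × sequence length,
this estimator is unbiased for the simulated ground truth regardless of how
many genomes a mOTU holds. The unassigned pool has no fixed gene set; its
per-family counts are normalized by the database-wide mean gene length of
the family — a documented stand-in choice. The mean (not median) over
families is used for small-fixture stability.

Rank aggregation keys taxa by the full `;`-joined lineage prefix, reports
mass from rank-unannotated mOTUs under `unannotated@<rank>`, and carries
the unassigned fraction through unchanged, so totals stay 1.

Rarefaction draws a multivariate-hypergeometric subsample (without
replacement, exact total) at depth 5000 by default; a depth exceeding the
sample total is an error rather than a silent pass-through. Sample QC drops
samples with fewer than 5000 mapped inserts (strict `<`); prevalence
detection requires the fraction of positive samples to exceed 0.1%
(strict `>`). Shannon diversity is −Σ p ln p in nats.

## Congruence machinery

Genome distances use bottom-s MinHash over canonical 21-mers (sketch size
1000, hash seeded): Jaccard j, Mash distance d = −(1/k)·ln(2j/(1+j))
(capped at 1 when sketches share nothing), ANI estimate 1 − d. These are
Mash-like defaults; the sketch estimator is reliable only while pairwise
divergence stays within roughly 15% — beyond that the 21-mer Jaccard
underflows, which bounds the divergence ranges used in fixtures.

Identity clustering of conserved loci and ANI clustering of genomes use the
same greedy centroid rule as the database (sorted by length then id; join
the first centroid at ≥ cutoff). The two-stage clustering of dedicated
dereplication tools is deliberately simplified to one stage.

The V-measure is computed from empirical entropies:
h = 1 − H(truth|pred)/H(truth), c = 1 − H(pred|truth)/H(pred),
V = 2hc/(h+c), with h = 1 when H(truth) = 0 and c = 1 when H(pred) = 0;
β is fixed at 1 (configurable). Distance–distance correlations are squared
Pearson correlations of *distances* (1 − identity), with marker-gene
distances averaged over the ten families before correlating; degenerate
(constant) columns yield NaN.

## Profile metrics

All metrics exclude the unassigned / rank-unannotated mass first (gold
standards enumerate named taxa only), renormalizing by default. F1,
completeness and purity operate on taxon-name sets (purity after an
optional prediction-abundance filter, default 0 — the reference
benchmarking tool's filter value is not published and is exposed as a
parameter); the L1 norm error is Σ|pred − gold| ∈ [0, 2]. The weighted
UniFrac error builds the taxonomy tree from the union of lineage paths with
unit branch lengths between consecutive ranks and sums |pred − gold|
subtree mass over edges. The sum-of-ranks composite ranks tools 0 = best
per (sample, rank, metric) cell with ties sharing the mean rank and sums
over cells. Spearman congruence concatenates union-aligned, zero-filled
abundance vectors across samples; constant vectors give NaN.

## Differential abundance

Taxa are kept when their maximum relative abundance over samples strictly
exceeds 0.1%. Each kept taxon gets a two-sided Wilcoxon rank-sum test —
exact when both groups have ≤ 25 samples and the taxon has no tied values,
otherwise the normal approximation with continuity and tie correction —
and Benjamini–Hochberg q-values. The generalized fold change is the mean
over the quantile grid 0.1–0.9 (step 0.1, linear/type-7 interpolation) of
log10 quantile differences with pseudo-count 1e-5 (the cited tool's
defaults; both exposed as parameters). Significance: q < 0.05 and
|gFC| > 1.

**Boundary caveat.** An effect whose true magnitude is exactly tenfold has
gFC strictly below 1 whenever the pseudo-count is positive — since
(10x+ε)/(x+ε) < 10 — and compositional renormalization shrinks it further
(measured expectation ≈ 0.99 on the cohort fixtures). A |gFC| > 1 call on
an exactly-tenfold effect therefore depends on sampling noise; effects
comfortably above tenfold are called reliably. Tests exercise both regimes.

## Synthetic fixtures: what they emulate, and what they do not

All generators are deterministic given (parameters, seed). Mutation is
substitution-only: a fixed number of positions sampled without replacement,
each changed to a different base, so realized identity equals the target to
within half a position — exact identity targeting is what makes the
threshold boundary probes meaningful. Indels, rearrangements and horizontal
transfer are not modeled.

- `make_species_clusters` uses disjoint substitution sites across genomes so
  within-species identities exceed between-species identities by
  construction, planting clusters that straddle the 96.5% boundary.
- `make_16s_like_genomes` confines the conserved locus's variation to a
  small variable-site set (default 10% of the locus) hit recurrently with
  back-mutations at 1/5 of the genome-wide rate. This produces genuine
  identity saturation and homoplasy — a locus mutated at a merely *reduced
  uniform* rate would remain perfectly linearly correlated with genome
  divergence, and the qualitative phenomenon (marker-gene distances track
  whole-genome distances better than conserved-locus distances, and
  conserved-locus clustering is coarser) would not emerge. The default
  divergence range (0–8% per genome against the ancestor) keeps pairwise
  divergence within the sketch estimator's reliable range.
- `simulate_inserts` draws reads from member MG sequences proportional to
  abundance × gene length with uniform start positions, binomial
  substitution errors and random strand. No quality-score model, chimeras,
  or non-marker genomic background: profiling specificity against non-MG
  DNA is *not* tested by these fixtures.
- `make_two_group_cohort` draws per-taxon log10 baseline means from a
  normal distribution (sd 1.0, sorted ascending so taxon indices are
  interpretable: `taxon_000` rarest), adds per-sample log-normal noise
  (default sd 0.2 in log10 units), multiplies group-B means by the planted
  fold changes, and renormalizes rows to sum to 1. Compositional closure is
  therefore present in the fixture, exactly as in real relative-abundance
  data.

Passing tests on these fixtures demonstrate correctness of thresholds,
estimators and clustering rules under controlled identity structure; they
do not demonstrate performance on real metagenomes (alignment ambiguity
between paralogs, uneven coverage, contamination and database incompleteness
are all absent).

## Problem sizes

The test-suite and acceptance computations use desk-scale sizes chosen to
exercise every rule: 3–5 species × 1–3 genomes for database fixtures,
1000 nt marker genes (0.1% identity steps are exact at this length),
communities of up to 10,000 inserts of 150 nt, 20–50 genomes of 20–40 kb
for sketch analyses, and cohorts of 20 samples per group × 50–100 taxa
(50 seeds for null-calibration checks).
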