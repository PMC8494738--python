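# Methods

This note documents the statistical procedures, the synthetic study design,
the numerical conventions, and the limits of what the tests demonstrate.

## Coordinate and binning conventions

All interval algebra is 0-based half-open (BED convention); GFF/GTF input is
shifted on read.  Book-ended intervals share no bases: "overlap" always
means intersection length ≥ 1 bp, so the cross-tissue pooling rule ("merge
regions overlapping by ≥ 1 bp") never joins regions that merely touch.
Segmentations are full partitions of the assembly on a 200-bp grid (the
terminal bin of a chromosome may be short); gaps in input BEDs are filled
with the quiescent state on read, and adjacent same-label rows are merged.

Genome tiling for module clustering lays `floor(length / tile)` full tiles
per chromosome from position 0 and drops the sub-tile remainder, so every
fragment has exactly the nominal length; chromosomes outside a configurable
allow-list (default: autosomes + X + Y, with or without a `chr` prefix) are
excluded as contigs.  `keep_remainder=True` switches to the
bedtools-makewindows convention.  On the bundled susScr11 chromosome sizes
these policies give 1205 and 1225 fragments respectively.

## Enrichment statistics

Fold enrichment is FE = (C/A)/(B/D) at base resolution, with the feature
flattened to its base-union before B and C are computed; A = 0 or B = 0
yields NaN rather than an error.  Significance uses a two-sided Fisher exact
test (point-probability convention, as in `scipy.stats.fisher_exact`) on a
2×2 table of 200-bp bins rather than bases, because base-level counts are
massively autocorrelated and violate the test's independence assumption; a
bin counts as state- or feature-covered when at least half of it is
overlapped.  Degenerate tables (a zero margin) return p = 1 with a warning.

TSS density profiles are strand-oriented (upstream negative; positions
genomically right of a minus-strand TSS are upstream) and normalized by the
state's genome-wide bin frequency, so a value of 1 means "no enrichment";
an absolute-frequency mode is available.  Windows truncated by chromosome
ends contribute only their available bins.

## State dynamics

Fragment state matrices average per-tissue state frequencies (state bins /
total bins) per fragment; columns are probability vectors.  Fragment
clustering is k-means (Euclidean, 25 seeded restarts, best
within-cluster-SS); the state rows are clustered with k = 3 alongside.
Module contrasts are Welch two-sample two-sided t-tests of each module's
per-fragment values against a reference module, with no multiplicity
adjustment (each module is one planned comparison); modules with fewer than
two fragments return NaN, and a zero-variance tie with equal means returns
t = 0, p = 1 by convention.

Variability curves: GL_t is the state's bp in tissue t, TGL the bp of the
1-bp-merged pooled regions; tissues are added in decreasing GL/TGL order
(ties alphabetical) and the curve is the running union over TGL —
non-decreasing and ending at 1.  Switching probabilities are bin-retention
ratios: P(A→B) = Obe/TbAe with Obe the bins carrying the state in both
tissues; the pair value is the mean of the two directions, and a direction
with no state bins is NaN.

Signal confidence scores are −log10 P(X ≥ k) for X ~ Poisson(λ), upper tail
inclusive, with λ the per-sample background mean per 200-bp window.
Epigenome clustering is agglomerative with Ward-D2 linkage on Euclidean
sample distances (scipy's `ward` on observations); samples are pre-sorted
by id so the tree is invariant to input order, and a constant matrix warns
before producing its (arbitrary but deterministic) tree.

## Tissue specificity

TSE detection: x = log2(TPM+1); each tissue column is standardized across
genes to mean 0, variance 1 (the column-wise reading of the ambiguous
"scaled within each tissue group" instruction; `scale="none"` gives the raw
reading).  For gene g and focal tissue t, t_g = (x_gt − mean(x_g,rest)) /
(sd(x_g,rest)·sqrt(1 + 1/n)), where the rest pool excludes every tissue in
t's sub-group (small intestine: jejunum/ileum/duodenum; large intestine:
cecum/colon; brain: cortex/cerebellum/hypothalamus; others singleton).  The
top ceil(0.05·G) genes by descending t (ties by gene id) are the TSE set.
A zero-variance rest pool maps to ±∞ sentinels: ranked first when the focal
value exceeds the constant, excluded otherwise.

RRAT construction merges one state's intervals across tissues under the
1-bp rule (transitive closure); presence(region, tissue) = 1 iff ≥ 1 bin of
the tissue's state overlaps the region.  Module assignment requires exact
set identity for the group modules (present in *exactly* the 5 intestinal
or *exactly* the 3 brain tissues) — without exclusivity the 17 categories
would not be disjoint — and any other multi-tissue pattern is reported as
`unassigned` outside the named universe.

## Enhancer–gene linking

Loops: each forward-strand CTCF motif hit pairs with its nearest
downstream reverse-strand hit within a 1-Mb span cap (convergent-orientation
rule); nested or overlapping candidate spans merge into their union, so the
final loop set is pairwise disjoint.  Note that under the nearest-partner
rule only nested/shared-anchor overlaps can actually arise; the merge
handles the general case regardless.  An optional peak-intersection filter
on motif hits is off by default.

Linking: for every enhancer (midpoint) and gene TSS co-resident in a loop,
Spearman's ρ of enhancer signal and TPM across tissues; p from the full
permutation null at n ≤ 9 (enumerated once per n and cached) and from the
t-approximation above; BH applied once over all loops jointly; pairs with
q < α kept, both signs by default (`positive_only` restricts to ρ > 0).
Constant rows are skipped with a log entry.  At n = 14 tissues the
t-approximation is known to be slightly anticonservative in the extreme
tail of the discrete rank statistic; on all-decoy simulations the realized
family-wise false-link rate sits around 0.06–0.09 at a nominal 0.05, while
the per-test rejection rate stays far below α.  This is a property of the
approximation, not of the BH step.

## Selection and GWAS

Windowed FST is the Hudson estimator aggregated as a ratio of averages
(mean per-SNP numerator over mean denominator), the form robust to
low-frequency variants; windows are 10 kb with a 10-kb step by default,
SNP-less windows are omitted and monomorphic windows score 0.  Selection
signatures are the top ceil(0.05·n) windows by FST, ties broken by genomic
order with a warning.  Their state enrichment delegates to the FE/Fisher
machinery with the signatures as the feature; eQTL SNPs enter the same
statistic as 1-bp features.

The cyclical permutation test marks the genome-ordered SNP list with
annotation membership, takes the mean association statistic of member SNPs
(mean rather than sum so annotations of different sizes are comparable; sum
available), and rotates the membership vector by a uniform offset in
[1, n−1] per permutation — rotation preserves both the annotation's
block structure and the statistics' local autocorrelation.  The empirical
p is (1 + #{null ≥ observed})/(1 + n_perm), never zero.  The implementation
precomputes the statistic under all n rotations and samples offsets, which
is algebraically identical to rotating per permutation.

## Cross-species conservation

200-bp segments get the coverage-weighted mean of a per-base score track
(uncovered segments are dropped and counted); segments are ranked ascending
into 50 sets whose sizes differ by at most one (remainder on the lowest
sets), set 0 = fastest changing.  Orthology maps are one-to-one aligned
interval pairs with an identity weight; lifting projects region pieces
through pairs with identity ≥ 0.65 piecewise-linearly (offset-scaled when
pair lengths differ) and reports sub-threshold or unaligned pieces as
unmapped, conserving total length.  The epi-conservation rate of a lifted
region is the fraction of its bases covered by the same state in the target
segmentation (0 = no overlap, 1 = fully occupied); curves average rates per
set, assigning each region to the set of the 200-bp segment containing its
source-coordinate midpoint (a length-weighted alternative would be the
natural extension; midpoint assignment was chosen for its simplicity).
Expression-conservation strata sort orthologous genes by a per-gene Welch
t-test p between two species' replicate TPMs, ascending (set 0 = most
divergent), into 50 equal sets; "20 kb around the TSS" is read as TSS ± 10 kb.

## The synthetic study design

The generator is a pure function of a config and a seed; one global seed
fans out to five fixed substreams (segmentation, expression, loops,
GWAS/FST, orthology) so stages regenerate independently.  Defaults emulate
the study's shape at desk scale:

- **Genome**: two chromosomes, 10 Mb total, 200-bp bins.  Genes (1000) are
  evenly spaced with alternating strands, TSSs on the bin grid.
- **Elements**: planted without overlap in the strong-enhancer state —
  20 all-common, 20 gut-common, 20 brain-common, 5 per-tissue-specific —
  plus 100 background elements of other non-quiescent states carried by
  random tissue subsets (background deliberately avoids the planted element
  state so sharing-module recovery is exact at zero noise).  Lengths are
  bounded-geometric on 200-bp multiples, mean ≈ 600 bp, matching the order
  of typical regulatory-element sizes.  Every gene TSS optionally carries a
  constitutive active-promoter bin in all tissues.
- **Expression**: log2(TPM+1) ~ Normal(3, 1) per cell; each tissue's 10
  planted TSE genes gain Δ = 5σ in that tissue.
- **Linking**: six 100-kb loops framed by convergent motif pairs; one
  planted enhancer per loop tracks a resident gene (signal = 2·TPM + noise,
  noiseless by default), four decoys per loop carry independent noise.
- **GWAS/FST**: 2000 grid SNPs with χ²(1) statistics, scaled ×3 inside an
  annotation of ~10% of SNPs in 20 blocks; FST windows follow Beta(0.5, 9.5)
  (mean ≈ 0.05, long right tail, a realistic genome-wide FST shape) with
  +0.4 planted in 5% of windows drawn among windows overlapping the planted
  element state, so selection signatures are genuinely state-enriched.
- **Orthology**: a 2-Mb source chromosome of iid per-segment states
  (quiescent 0.6, rest uniform), per-segment conservation scores defining
  the 50 sets, and a target copy whose segments flip to a random other
  state with probability given by a U-shaped profile over sets
  (0.75 − 0.65·x², x ∈ [−1, 1]: high turnover at neutral sets, low at both
  extremes).  The orthology map pairs equal coordinates in 1-kb blocks,
  10% of which are planted below the 0.65 identity threshold.

What the generator does *not* emulate: read-level noise, peak-calling
artefacts, segmentation errors correlated across tissues, linked-SNP LD
structure beyond block membership, indel-containing alignments (map pairs
are length-preserving by default), or biological correlation between
expression and chromatin beyond the planted effects.  Passing tests
therefore demonstrate the correctness and calibration of the procedures
under the planted model, not robustness to every artefact of real
consortium data.

## Problem sizes and determinism

The test suite and the reproduction script run the study at the sizes
above (10-Mb genome, 1000 genes, 2000 SNPs, 2-Mb orthology chromosome);
Monte-Carlo calibrations use 1000 null cohorts (199 rotations each), 100
power cohorts (999 rotations) and 200 linking cohorts, completing in tens
of seconds.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` substreams; fixed seeds give byte-identical
outputs.  Known numerical conventions: empirical p-values use the +1
correction; TSE and top-window ties break deterministically (gene id,
genomic order); k-means uses 25 seeded restarts; Hudson FST of identical
finite samples is slightly negative (unbiased estimator), clamped only on
request.
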