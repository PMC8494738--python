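# chromdyn

Cross-tissue chromatin-state analytics for multi-tissue functional-annotation
studies: enrichment statistics, genome-scale state dynamics, tissue-specific
regulatory element calling, CTCF-loop enhancer–gene linking, selection and
GWAS signal enrichment, and cross-species epigenome-conservation scoring.

## The problem

Segmenting a genome into chromatin states (active promoter `TssA`, strong
enhancer `EnhA`, Polycomb-repressed `Repr`, quiescent `Qui`, …) per tissue is
only the start; the biology lives in what happens *across* tissues and
species.  Given 14 tissue segmentations over a 15-state vocabulary (five
intestinal tissues, three brain tissues, six singletons), this package
answers the downstream questions:

- How enriched is each state in genomic features, and around TSSs?
  Fold enrichment is the base-level ratio **FE = (C/A)/(B/D)** — C overlap bp
  between a state (A bp) and a feature (B bp) on a genome of D bp — with a
  two-sided Fisher exact test on 200-bp bins for significance.
- Which 2-Mb genome fragments share a state composition?  Fragments are
  k-means-clustered (k = 12 at full scale) on their tissue-averaged
  state-frequency vectors, and per-module expression/methylation is
  contrasted against a reference module by Welch t-tests.
- How variable is a state across tissues?  Its regions are pooled over
  tissues with a 1-bp overlap merge (the *RRAT*); the cumulative coverage
  curve aGL/TGL, adding tissues in decreasing-coverage order, separates
  constitutive from tissue-restricted states.  Pairwise switching
  probabilities are bin-retention ratios Obe/TbAe.
- Which RRAT regions are tissue-specific?  Each region's binary
  tissue-presence vector maps to one of **17 sharing modules**: all-common,
  gut-common (exactly the 5 intestinal tissues), brain-common (exactly the
  3 brain tissues), or one of 14 tissue-specific modules.
- Which genes are tissue-specifically expressed (TSE)?  A one-vs-rest
  t-statistic on column-standardized log2(TPM+1), excluding same-sub-group
  tissues from the rest pool; the top 5% per tissue are its TSE genes.
- Which enhancers drive which genes?  Convergent CTCF motif pairs define
  loops (nested/overlapping spans merged); every enhancer–gene pair inside a
  loop is scored by Spearman correlation of enhancer signal and expression
  across tissues, with Benjamini–Hochberg control at FDR 0.05.
- Are selection signatures and GWAS hits concentrated in regulatory states?
  Hudson FST in 10-kb windows (ratio of averages) yields top-5% selection
  signatures fed to the same FE statistic; GWAS enrichment uses a genotype
  cyclical-permutation test that rotates the SNP–annotation membership
  vector along the genome-ordered SNP list (10,000 rotations), preserving
  local correlation.
- Is the epigenome conserved where the sequence is?  200-bp segments are
  ranked into 50 conservation sets by mean score; state regions are lifted
  between assemblies through a reciprocal-best orthology map (identity
  ≥ 0.65) and each region's epi-conservation rate is the fraction covered by
  the same state in the target species.

A first-class synthetic-data module generates the whole study design with
planted ground truth (shared/group/specific elements, TSE effects,
enhancer–gene links, inflated GWAS statistics, shifted FST windows,
class-dependent state turnover), so every stage is testable without any
consortium download.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/06_selection_and_gwas.py --seed 1
```

The selection/GWAS driver prints:

```
600 windows; top 5% = 30 signatures; 30/30 planted high-FST windows recovered
signature fold enrichment: EnhA 7.59 vs Qui 0.99
GWAS enrichment: observed mean chi2 3.24 in 198 annotated SNPs, permutation p = 1.00e-04
```

Reading: the Hudson-FST scan over 600 10-kb windows recovers every planted
selection signature; those signatures are 7.6-fold enriched in the strong
enhancer state (they were planted over enhancers) while quiescent background
sits at FE ≈ 1; and the mean χ² of SNPs inside the planted annotation (3.24
versus ≈ 1 genome-wide) is higher than in all 10,000 membership rotations
(empirical p = 1e-4).  The conservation driver similarly reports the
epi-conservation curve over the 50 sequence-conservation sets tracking the
planted turnover profile with |Spearman ρ| ≈ 0.95.

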