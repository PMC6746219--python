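# Methods

This note documents the models, parameter choices and numerical conventions in
`allosrna`, and what the synthetic validation does and does not demonstrate.

## Study design being modelled

Two diploid parents contribute subgenomes A and C to an allopolyploid F2; each
genotype is sequenced as small-RNA libraries in three biological replicates.
The additive expectation for any feature is the mid-parent value (MPV), the
arithmetic mean of the parental expression levels; a feature is non-additively
*activated* or *repressed* when the F2 significantly exceeds or falls short of
the MPV, and *high-* or *low-parent* when it lies outside the parental range.

## Pipeline conventions

* **Adapter trimming** is exact-match: the longest read suffix equal to a
  prefix of the 3' adapter (≥ 6 nt) is removed, symmetrically at the 5' end.
  No mismatch tolerance and no quality trimming — exactness keeps the stage
  fully checkable, and the generator writes adapters verbatim.
* **Length filter**: 18–30 nt inclusive, reads with N discarded.
* **Structural-RNA removal** matches reads as exact substrings of the
  structural reference *or its reverse complement*; strandedness of the
  contaminants is unknown, so removal is conservative.
* **Alignment** is exact and full-length on both strands, via an 18-mer seed
  index with full verification (equivalent to, and tested against, a naive
  two-strand scan). Multi-mapped reads are reported with `unique=False`;
  uniqueness is defined over the genome the sample was aligned to. A minimal
  SAM import path (`align.hits_from_sam`) accepts external aligner output.
* **miRNA counting** uses all reads (unique and multi-mapped) overlapping a
  mature locus by ≥ 1 nt, because conserved miRNAs planted in both subgenomes
  are inherently multi-mapped in the merged F2 reference; a
  `mirna_unique_only` switch restores unique-only counting. A read overlapping
  two distinct miRNAs counts for both; planted loci are spaced so this cannot
  occur in the synthetic studies.
* **Cluster calling** is two-phase: connected components of strictly
  overlapping read intervals, a support threshold of ≥ 3 reads counted with
  collapse multiplicity (`min_distinct` offers the distinct-sequence variant),
  then iterative merging of surviving clusters with gaps ≤ 200 nt (inclusive
  at exactly 200). Clusters are strand-agnostic, called on the pooled hits of
  all samples so every sample is quantified on identical intervals. Note the
  post-merge cluster *count* is not monotone in the support threshold
  (dropping a weak bridge component can split a merged cluster); containment
  and total supporting mass are the monotone quantities.
* **RPM** = raw count / clean-library total × 10⁶, computed per library.

## The non-additivity model

`NonAdditivityModel` compares each F2 sample against the MPV per feature.

**Count level (miRNAs), `method="ztest"`.** Replicate counts are pooled per
genotype. The MPV pseudo-sample rescales each parent's pooled count to the
pooled F2 depth and sums them over a pseudo-depth of 2 × n_F2, so the
estimated pseudo-proportion is exactly the average of the parental proportions
*and* the binomial variance the two-proportion z-test assumes matches the
pseudo-sample's true sampling variance (averaging over a pseudo-depth of n_F2
would make the test conservative by a factor √0.75 on the z-scale). The test
is the DEGseq-style pooled two-proportion z-test; both-zero features give
p = 1.

**Replicate level (siRNA clusters), `method="ttest"`.** Replicate i of each
parent is averaged into an MPV replicate; F2 replicate RPMs are compared with
MPV replicate RPMs by a two-sided pooled-variance Student *t*-test.
Zero pooled variance is resolved by convention: p = 1 for equal means, p = 0
otherwise.

P-values are Benjamini–Hochberg adjusted per F2 sample across tested features
(via `statsmodels.stats.multitest`, cross-checked against a direct step-up in
the tests). A call requires p ≤ α **and** FDR ≤ α_FDR (both default 0.05,
applied conjunctively). Features with zero counts in both F2 and MPV are
untestable and excluded from the FDR family but reported. log2(F2/MPV) uses a
+0.25 RPM offset on both sides to keep zero-expression features finite
(configurable, `log2_offset`). Dominance is classified for every tested
feature regardless of significance.

## Target prediction and enrichment

The target scanner is an intentionally simplified, ungapped variant of the
psRNATarget expectation score: per position, Watson–Crick pair 0, G:U wobble
0.5, mismatch 1; penalties at miRNA positions 2–13 (1-based from the 5' end)
are doubled; a site is reported at expectation ≤ 5.0 (the tool family's
classic default). No bulges, gaps or accessibility term — output headers label
the scores accordingly. GO enrichment is the plain upper-tail hypergeometric
test with BH-FDR ≤ 0.05 over all annotated terms; no gene-length correction is
applied (target sets are gene-level, not read-level, here) and the annotation
is taken as already propagated.

## The synthetic-data generator

`SimConfig` defaults define the reference study:

| parameter | default | meaning |
|---|---|---|
| `n_mirna_loci` | 50 | conserved miRNAs, identical 21-mer planted in A and C |
| `n_sirna_loci` | 150 | subgenome-private siRNA loci (100–500 nt) per subgenome |
| `n_chrom_a/c`, `chrom_len` | 3, 60 kb | desk-scale genomes; loci ≥ 400 nt apart |
| `read_depth` | 50 000 | reads per library |
| `n_replicates` | 3 | replicates per genotype |
| `frac_nonadditive` | 0.1 | fraction of features with a planted F2 effect |
| `effect_log2fc` | 2.0 | planted |log2 F2/MPV| |
| `dispersion` | 0.0 | NB overdispersion (0 = Poisson limit) |
| `structural_frac` | 0.05 | contaminant reads |
| `mirna_mutation_frac` | 0.05 | miRNA reads carrying 1–2 substitutions |

Counts are gamma-Poisson around each genotype's true means, conditioned on the
exact library depth (multinomial over gamma-jittered weights). The Poisson
default reflects that the z-test under study assumes count-level sampling
noise; positive `dispersion` is available to stress the statistics and makes
the z-test anticonservative, as expected for DEGseq-style tests.

Two design choices follow from the fact that fixed-depth sequencing measures
*relative* abundance:

1. **Common expressed mass.** Each genotype's mean vector is scaled to a
   common total, so parental proportions and the F2's additive expectation are
   exactly comparable and planted categories keep their sign (guarded by a
   validation error for pathological, fully one-sided configurations).
2. **Mass-balanced direction prior.** An activated locus adds (2^e − 1) × MPV
   of library mass while a repressed one removes only (1 − 2^-e) × MPV; with
   50/50 signs the planted effects would inflate the F2 library total by
   ≈ 11% (frac 0.1, e = 2), making every feature's relative abundance
   genuinely non-additive. Directions are therefore drawn with
   P(activated) = (1 − 2^-e) / ((2^e − 1) + (1 − 2^-e)) (0.2 at e = 2), the
   symmetric construction standard in differential-expression simulators under
   total-count normalisation. The residual per-draw imbalance scales as
   1/√(number of features) — one reason the default study has 350 features
   rather than a handful.

**Compositional coupling remains a real, documented effect**: in any given
draw the net planted mass is not exactly zero, so truly additive features
shift coherently by the total-mass ratio, and with deep libraries the z-test
correctly detects shifts of a few percent. In the default recovery study this
produces a small number of weak-|log2FC| calls on additive features (reported
as `recovery_false_positives` by the acceptance script). This is a property of
RPM/total-count normalisation itself — the same mechanism by which a genuine
siRNA surge in a hybrid dilutes the apparent expression of everything else —
not of the simulator alone.

What the generator does **not** emulate: sequencing errors beyond the planted
miRNA substitutions, quality-score structure, chimeric reads, isomiR
heterogeneity, hairpin precursors (novel-miRNA discovery is out of scope), and
genuinely shared siRNA loci between subgenomes. Passing recovery tests
therefore demonstrate the pipeline's statistical and algorithmic correctness
under the stated model, not robustness to artefacts absent from it.

## Problem sizes and determinism

The validation suite runs at desk scale: 10-kb oracle fixtures for cluster
calling and alignment, 2 400 features for null calibration, and a full
pipeline recovery study at 10⁵ reads × 9 libraries over 350 features
(≈ 25 s). All stochastic stages consume a `numpy` `SeedSequence` derived from
(`seed`, genotype, replicate), so identical configurations give byte-identical
FASTA/FASTQ/GFF and result tables; the pipeline re-run is asserted
byte-identical in the tests.

## Known limitations

* The exact matcher is designed for desk-scale genomes (seed index in memory);
  real chromosome-scale work should import external aligner output via the SAM
  path.
* MPV testing at count level inherits DEGseq's limitations: no biological
  replicate variance enters the z-test (the t-test path covers replicated
  RPMs), and overdispersed counts inflate its type-I rate.
* The ≤ 2-mismatch conservation rule and the ungapped target scanner are
  deliberately simple surrogates for miRBase curation and full psRNATarget
  alignment, respectively.
* Enriched-term counts depend entirely on the annotation supplied; the
  built-in annotation generator plants a single target-associated term.
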