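# Methods

This note documents the models, procedures and numerical choices behind
`stressig`, and what the synthetic-data tests do and do not establish about
behavior on real data.

## Coordinate and data conventions

All genomic coordinates are 0-based, half-open (BED convention), on a single
synthetic chromosome in generated data. Peak sets are data frames in a
"BED6+2" layout: chrom, start, end, name, score, strand, log2FC, adjusted p.
The adjusted p column is an *input*: peak-level differential statistics are
assumed to come from an upstream peak caller / count model, and this package
does not re-derive them from read counts. Overlap computations ignore strand;
TSS distances are signed by gene strand (negative = upstream). Ties are
broken everywhere by (chrom, start, end, name) so outputs are deterministic.

## Interval operations

Intersection uses a chromosome sweep over both sets sorted by start, with a
cache of candidate intervals pruned as the sweep advances; a pair is emitted
when the shared interval `[max(starts), min(ends))` spans at least
`min_overlap_bp` (default 1 bp — the minimum overlap used by the original
intersection step is not documented, so the most permissive setting is the
default). Shared differential regions expose two gates on one operation — an
adjusted-p threshold (default 0.05) and a top-N-by-score cut (default 200) —
because the two upstream peak pipelines this mirrors differ only in their
ranking statistic. Annotation reports, per peak, every overlapping enhancer
record with its target genes plus the nearest TSS by midpoint distance; the
candidate catalog of a region set is the union of its enhancers' targets,
falling back to the nearest-TSS gene for regions with no enhancer hit.

## Statistical primitives

* **Normalization**: median-of-ratios size factors (per-gene geometric-mean
  reference, genes with any zero excluded; the median is taken in linear
  ratio space), or CPM. The log transform used throughout is log2(x+1) on
  normalized counts — a variance-stabilizing stand-in for model-based
  regularized logs, which are tool-specific.
* **Differential expression** is a Welch t-test on that log scale with BH
  adjustment. This deliberately replaces a negative-binomial GLM: the DE call
  here is a gate feeding bespoke selection steps, and a dependency-free test
  keeps the pipeline auditable end-to-end. The gates themselves
  (|log2FC| > 1, FDR < 0.05) are unchanged. Consequence: genes with very
  large within-group dispersion essentially cannot pass a Welch gate at
  n = 5/group, so the downstream SD filter acts as a robustness backstop and
  fires mainly on genes with large, systematic within-group splits.
  Zero-variance genes get p = 1 when group means are equal (p = 0 otherwise)
  and are flagged, not dropped silently.
* **Multiple testing**: Holm step-down for gene-pair correlations, BH for DE
  — the assignment the derivation procedures specify. Implementation is
  statsmodels' `multipletests`; the test suite checks both against literal
  step-down/step-up oracles.
* **Pairwise Pearson**: r for every unordered pair, p from the
  t-transformation with n−2 df, Holm across all pairs. The 0.05 pair gate is
  applied to the *adjusted* p by default (the procedure states Holm
  adjustment alongside the gate without saying which scale the gate uses;
  a `use_adjusted=False` flag exposes the other reading).
* **Mann-Whitney U**: midrank ties; exact two-sided p by exhaustive
  enumeration of all C(n1+n2, n1) assignments when n1·n2 ≤ 64 (valid under
  ties), otherwise a normal approximation with tie and continuity
  corrections.
* **2^-ddCT**: ΔCT = target − housekeeping per condition, ΔΔCT =
  experimental − control, fold = 2^(−ΔΔCT). Cycle-threshold units.

## Signature derivation

The correlation-frequency selection counts, per candidate gene, the number
of significant correlated pairs containing it, then competition-ranks the
counts (ties share the better rank, alphabetical order stabilizes output).
"Top half" is interpreted as: among genes with at least one significant pair
(zero-count genes excluded), keep genes at the best ⌈d/2⌉ of the d distinct
ranks. Both gates are parameters and every stage's cardinality is recorded in
the signature's provenance, because the original 54 → 18 reduction is not
reconstructable from a literal halving and the implemented rule must be
auditable. Survival direction per selected gene is a best-cutoff-dichotomized
binary Cox fit — matching the methodology used for every survival claim this
pipeline mirrors — rather than a continuous-covariate fit; hazardous
(HR > 1) genes form the up list, protective genes the down list. The naming
(hazardous/protective) is deliberate: "positively/negatively correlated"
reads differently in co-expression and survival contexts.

## Scoring

Rank scores follow the singscore idea: per sample, all G genes are midranked;
for a set of size k the mean rank lies in [(k+1)/2, G−(k−1)/2], so the
normalized score is (mean_rank − (k+1)/2)/(G−k) ∈ [0, 1]; a down set is
scored the same way, negated, giving a combined range of [−1, 1]. Scores are
invariant to any strictly monotone per-sample transform. Inducibility
classes use a z-band of ±0.5 on standardized scores (the source analysis
shows a ranked bar plot without a numeric boundary; 0.5 SD is the package's
choice and is a parameter). The mean-expression score feeding survival is
mean(up) − mean(down) on the log scale, i.e. down genes are inverted. The
per-cell set score bins genes by mean expression into 25 bins and samples 50
control genes per set gene (seeded), following the convention of the
standard single-cell scoring tool.

## Survival

Kaplan-Meier is the product-limit estimator; the median is the smallest
event time with S(t) ≤ 0.5 (undefined if never reached). The log-rank test
uses the hypergeometric variance. The Cox fit is a single binary covariate
maximized by Newton-Raphson on the Breslow partial likelihood to
|Δβ| < 1e−8 (≤ 50 iterations); Breslow rather than Efron because the
simulations are tie-free, making the choice immaterial there, and Breslow is
the simpler documented standard. Complete separation is detected, β capped
at ±10 and flagged. Best-cutoff scans every distinct score value whose split
leaves both groups within the [0.25, 0.75] cohort-fraction band (the band the
emulated tool scans is unpublished; it is a parameter), minimizes the
log-rank p, breaks ties toward the median score, and reports the number of
cutoffs scanned. No multiplicity correction is applied — deliberately, to
mirror the emulated tool — so the reported minimum p is optimistic relative
to a pre-specified split; this is a documented caveat, and with
lower_q = upper_q = 0.5 the procedure reduces to a median split.

## Single-cell stage

QC gates run in a fixed order: cells with < 200 detected genes; genes
detected in < 10 cells; cells with mitochondrial or ribosomal count fraction
> 15% (the two families are gated *separately* at 15% each — the source
phrasing is ambiguous between combined and separate thresholds; both
thresholds are parameters); cells above the 98th percentile of
detected-gene counts. Metrics are computed on the matrix as it stands when
each gate runs. Normalization scales each cell to the median total count,
then log1p. Extreme stratification is performed on the pooled malignant
population (the reported per-group cell count is consistent only with
pooling across treatment arms): exactly ⌊qN⌋ cells per extreme, ties broken
by library size then cell id. The enrichment fold is the proportion ratio
[n(High, treated)/n(treated)] / [n(High, naive)/n(naive)], with a Haldane
+0.5 correction only when a zero cell occurs (flagged); an odds-ratio
variant is behind a flag, since the original fold is not written as a
formula. The CNV score is a windowed relative-expression summary — cell
log-expression minus reference-cell mean, clipped at ±3 reference SDs,
averaged over 250 consecutive genes in genomic order — retaining the
sliding-window principle of HMM-based CNV callers without the HMM; burden is
the mean squared profile. Batch correction, doublet removal, automated cell
typing and graph clustering are out of scope; their outputs (patient,
treatment, cell-type labels) are inputs here.

## The synthetic-data generator

The generator emulates the *structures* the analyses assume, with planted
answers:

* One chromosome; genes every 40 kb; each enhancer anchored 5–18 kb from a
  distinct gene's TSS (guaranteeing mutual disjointness), linked to 1–5
  target genes. The 14 shared-responsive enhancers partition the 54
  candidate genes among themselves, so every candidate is reachable from a
  shared enhancer by construction.
* ChIP peaks at responsive enhancers carry adjusted p log-uniform in
  [1e−30, 10^−1.5] (below the 0.05 gate with certainty — recovery power 1 by
  construction); background peaks draw adjusted p uniform on (0.05, 1], so
  the 0.05 gate separates planted from background exactly. Accessibility
  peaks cover the shared enhancers in inducible lines only; both line
  classes share a housekeeping-promoter background.
* Counts are negative binomial with log-normal gene means (median 200,
  log-SD 0.8 for bulk; per-cell means median 0.5 for single cell) and
  dispersion 0.02 by default — representative of a tightly controlled
  cell-line panel, and chosen so the planted 2-log2FC effect is recoverable
  through a Welch gate at n = 5 per group. Planted signature genes have
  their base means floored at 150 counts so recovery tests exercise the
  statistical gates rather than count sparsity.
* The tumor cohort (n = 177) carries a latent Bernoulli(0.5) activation
  factor: hazardous module genes shift up and protective genes down by
  2 log2 units when active, which simultaneously induces the co-expression
  block the pair-correlation stage must find. Event times are exponential
  with rate λ0·HR^a (baseline median survival 24 months, HR 6); censoring is
  independent uniform on (0, τ] with τ solved numerically so the expected
  censored fraction is 40%.
* Single-cell data: 12 patients (6 naive, 6 treated), 85% epithelial cells,
  5% of them a normal-adjacent subset; a high-program state (strongly
  elevated ITGB3-analog, elevated program genes) occurs with per-arm
  probabilities in the planted 62:1 ratio and pooled frequency 12% — just
  above the 10% stratification decile, so the top decile samples from within
  the program state instead of straddling its boundary. Dedicated MT/ribo
  gene families sit near 6–8% of counts, with a forced 2% of cells pushed
  above the 15% MT gate; malignant cells carry a 500-gene amplified block as
  CNV signal.
* One global seed fans out to fixed per-stage child seeds, so each stage is
  independently reproducible and bit-identical under a fixed seed.

**What passing tests do not show.** The generator has no batch effects,
doublets, ambient RNA, cell-cycle structure, spatial organization,
non-proportional hazards, or informative censoring; peak scores and
adjusted p values are drawn, not derived from read counts; co-expression
arises from a single latent factor rather than a regulatory network. Planted
recovery therefore validates the *correctness of the procedures and their
composition*, not robustness to real-data pathologies.

## Problem sizes used in checks

The test suite and the acceptance script run the full pipeline at the study
scale (2,000 genes, 14/54/18 planted structure, 177 tumors) over 20 and 10
seeds respectively; hazard-ratio recovery uses a 600-gene universe (the
survival component is independent of gene count) at 100–200 replicates per
generating HR; enrichment recovery uses 50,000 cells with a 300-gene
universe, where only the stratification gene and program genes matter.
These sizes were chosen so each check has clearly sufficient power at the
planted effect sizes.

## Known limitations

* The best-cutoff HR is optimistic by construction (minimum over a scan);
  the package reports the number of cutoffs scanned but, like the emulated
  tool, does not correct for it.
* The Welch-t DE stage is not a substitute for count-model inference at very
  low counts or tiny n; it is the documented gate of this pipeline.
* `select_top_half` encodes one defensible reading of an under-specified
  selection rule; provenance makes the applied rule auditable, and the gates
  are parameters.
* CLI configuration covers the generator and the two pipeline gates; deeper
  stage parameters are library-level arguments.
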