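# stressig

Discovery and scoring of stress-responsive regulatory gene signatures in
pancreatic ductal adenocarcinoma (PDAC), built around the idea of
**STAT-open regions**: genomic sites that are bound by activated STAT3
(pY705) under inflammatory or hypoxic stress *and* lie in chromatin that is
accessible only in cell lines able to induce the stress program. Whether a
tumor cell can respond to STAT3 signaling is gated by enhancer
accessibility — e.g. the two *ITGB3* enhancers 13.6 kb upstream and 51.6 kb
downstream of its TSS — so gene expression patterns downstream of those
enhancers can stratify patients by their capacity for stress adaptation.

The package is aimed at computational biologists who want to run, audit, or
stress-test this style of multi-omic signature derivation. It implements the
complete analysis chain as composable library modules plus a CLI, and ships a
synthetic-data generator that plants a known answer at every stage, so the
whole pipeline is testable end-to-end without any external downloads:

| module | what it does |
|---|---|
| `stressig.synthdata` | planted-truth generators: ChIP/ATAC peak sets, enhancer map, cell-line panel, tumor cohort with survival, single-cell counts |
| `stressig.intervals` | BED I/O, sweep-line interval intersection, top-N peak ranking, enhancer/nearest-TSS annotation, STAT-open region derivation |
| `stressig.stats` | size-factor/CPM normalization, Welch-t differential expression, Holm/BH adjustment, all-pairs Pearson, exact Mann-Whitney, 2^-ddCT, z-scores |
| `stressig.signatures` | the inducibility signature (DE gates + SD filter) and the STRESS signature (correlation-frequency ranking + survival direction) |
| `stressig.scoring` | rank-based signature scores, inducibility classification, mean-expression scores, subtype z-scores, bin-matched per-cell set scores |
| `stressig.survival` | Kaplan-Meier, log-rank, binary-covariate Cox (Breslow), censor-at-threshold, auto best-cutoff stratification |
| `stressig.scrna` | single-cell QC gates, extreme-decile stratification, extreme-group DE, treatment-enrichment fold, windowed CNV score |
| `stressig.cli` / `stressig.pipeline` | subcommand CLI and end-to-end orchestration with manifests |

## The core derivations

**STRESS signature.** Differential STAT3-binding peaks from two stress
conditions (cytokine and hypoxia) are thresholded at adjusted p ≤ 0.05,
reduced to their top-200 peaks by score, and intersected; the shared regions
are filtered to those accessible in inducible but not non-inducible lines
(STAT-open regions); candidate genes are cataloged through a
GeneHancer-style enhancer→gene map. In a tumor cohort, Pearson correlations
r(g_i, g_j) are computed for every candidate pair with two-sided p from
t = r√((n−2)/(1−r²)) and Holm adjustment; genes are ranked by how many
significant pairs contain them, the top half of the distinct ranks is kept
(zero-count genes excluded), and each selected gene is called *hazardous*
(HR > 1) or *protective* (HR < 1) by a best-cutoff-dichotomized Cox fit.

**Inducibility signature.** Welch-t differential expression between lines
that can vs. cannot induce the program, gated at |log2FC| > 1 and
BH-FDR < 0.05, then dropping genes whose within-group SD on the
log2-normalized scale exceeds 2 in either group; upregulated survivors form
the signature. Samples are scored by the normalized mean rank of signature
genes and classified by z-score bands.

**Survival stratification.** Signature scores (mean of up-genes minus mean
of down-genes on the log scale) are dichotomized at the cutoff minimizing
the log-rank p over all splits inside the interquartile band; the hazard
ratio comes from a single-binary-covariate Cox partial likelihood
(Newton-Raphson, Breslow ties). No multiplicity correction is applied to the
cutoff scan, mirroring the web tool this emulates; the number of cutoffs
scanned is always reported.

## Worked example

```python
import stressig as sg

report = sg.pipeline.full_synthetic(sg.SimConfig(seed=1))
print(report["n_regions_recovered"], "/", report["n_regions_planted"], "regions")
print(report["n_recovered_correct_direction"], "/", report["n_module_genes"],
      "module genes with correct direction")
print(f"HR = {report['signature_hr']:.2f}, log-rank p = {report['logrank_p']:.2e}")
```

prints

```
14 / 14 regions
18 / 18 module genes with correct direction
HR = 6.63, log-rank p = 4.48e-19
```

The generator planted 14 shared stress-responsive enhancers fanning out to
54 candidate genes, hid an 18-gene co-expressed module (10 hazard-associated,
8 protective) among them, and gave the tumor cohort (n = 177) a latent
activation factor with hazard ratio 6. The pipeline recovered all 14 regions
exactly, cataloged all 54 candidates (1,431 gene pairs, 153 Holm-significant),
selected exactly the 18 module genes with every hazard direction correct, and
the derived signature's best-cutoff split estimates an HR of 6.63
(CI95 4.2–10.6) against the generating value of 6.

The same run is available from the shell, with all artifacts
(BED/TSV/GMT/JSON plus a manifest with checksums) written to disk:

```bash
stressig full-synthetic --seed 1 --outdir out/
```

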