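# pharmotype

Integrative ex vivo drug-response (pharmacoscopy) and proteotype analysis
for myeloproliferative-neoplasm (MPN) cohorts, with a seeded synthetic-cohort
generator that plants known effects at every level so the whole pipeline can
be validated end to end.

## Who this is for

Computational biologists analyzing image-based ex vivo drug screens of
patient blood cells together with per-cell-type proteome (DIA) matrices and
clinical annotation (disease cohort, driver mutation, variant allele
frequency). The package covers the full analysis chain:

* **pharmacoscopy** — feature-based single-cell classification (HSPC/CD34+,
  T-cell/CD3+, monocyte/CD14+, other) and live/dead gating; per-well
  cell-type fractions and oncogenic-marker-positive fractions (mutant-CALR or
  pSTAT5 stain above a per-patient threshold); a 0.3% control-HSPC patient QC
  rule; and per patient x drug relative-depletion scores

      r = 1 − mean(f_drug) / mean(f_control)

  against the matched vehicle controls (DMSO / PBS / isotype), with a
  two-sided pooled-variance Student's t-test on well-level values, the signed
  significance sign(r)·(−log10 p), and responder / non-responder / resistant
  classification.
* **proteotype** — log2 normalization and per-protein summarization, robust
  outlier flags, the group-structured missingness filter (keep a protein if
  observed in ≥ 90% of at least one group), left-censored imputation at the
  per-protein minimum with up to 5% upward noise, hemoglobin-contamination
  regression (every protein replaced by its residual against the mean
  HBA/HBB/HBD level), and proteotype Euclidean distances.
* **signature** — repeated recursive feature elimination: 100 seeded runs of
  stratified 70/20/10 split → 6-fold CV-RFE to 30 proteins → grid-tuned
  multilayer-perceptron classification → one test pass; the minimal signature
  is the set of proteins selected in ≥ 85 runs.
* **association** — per-protein ANOVA against clinical factors with optional
  confounders, two-group volcano t-tests, a from-scratch preranked GSEA
  (weighted Kolmogorov–Smirnov running sum, gene-label permutation null,
  NES), and factor–protein–pathway network assembly with physical-interaction
  edges at score > 0.7.
* **integrate** — drug–proteome Spearman correlation with enrichment,
  drug–clinical ANOVA counting, responder-proteome signatures, the
  MCM4/MCM7-anchored replicative signature and low/medium/high patient
  categorization, VAF–protein correlations stratified by driver, and the
  homozygous-CALR (VAF ≥ 75%) drug differentials.
* **synth** — the generator behind all validation: group-structured
  proteomes, VAF-scaled and anchor-coregulated blocks, hemoglobin
  contamination, left-censored + MCAR missingness, pharmacoscopy plates with
  planted per-patient drug kills, gene sets and interaction edge lists, all
  with machine-readable ground truth.

## Worked example

`examples/02_pharmacoscopy_scoring.py` simulates a 20-patient MF screen in
which one of six drugs carries a planted HSPC kill (survival multiplier 0.5),
then runs classification, gating, QC and scoring:

```
cell classifier: accuracy 0.989, viability accuracy 0.989
QC: 20/20 patients included

per-drug HSPC depletion (drug_01 carries the planted kill):
         median_r  responders
drug
drug_01     0.494          20
drug_02    -0.031           1
drug_03    -0.017           0
drug_04    -0.024           1
drug_05    -0.034           1
drug_06    -0.018           2
```

The planted halving of viable HSPCs is recovered as a median relative
reduction of 0.494 with every patient classified a responder; the null drugs
sit at r ≈ 0 with responder counts at the false-positive level. The other
`examples/` scripts walk through simulation, proteome processing, signature
selection, association/GSEA and the integration analyses the same way.

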