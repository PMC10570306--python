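# Methods

This note documents the models and procedures implemented in `pharmotype`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Pharmacoscopy scoring

**Cell model.** Each detected cell carries five features: nuclear stain,
a multiplexed lineage channel (CD3/CD14), CD34, an oncogenic-marker channel
(mutant-CALR for CALR-driven disease, pSTAT5 for JAK2-driven disease) and
nuclear area. A multinomial logistic regression on log-transformed features
assigns one of four classes — HSPC (CD34+), T-cell (CD3+), monocyte (CD14+),
other (marker-negative) — and a second logistic model makes the live/dead
call. This is deliberately a feature-based classifier: it operates on
per-cell summary features rather than raw image pixels, which is sufficient
for the well-level statistics downstream and keeps training to seconds. The
training report carries held-out accuracy and per-class sensitivity.

**Well summaries.** Per well: viable-cell count, class fractions (summing to
1 over viable cells), the oncogenic-marker-positive fraction among viable
cells, and mean channel intensities, also reported after per-patient z-score
normalization across that patient's cells (z-scoring after viability
gating). The marker-positivity threshold is set per patient as the geometric
midpoint between the median oncogenic intensity of T-cells (the in-sample
negative reference) and of HSPC+monocyte cells, over vehicle-control wells;
the threshold used is recorded in the output. Mean and summed intensities
are carried alongside the positive fraction so either can serve as the
oncogenic readout; the positive fraction is the default.

**Patient QC.** A patient enters drug-response analysis only if the mean
HSPC fraction over its DMSO control wells is at least 0.003 (0.3%); the
boundary is closed at the threshold. Wells with zero viable cells are
flagged invalid and excluded.

**Drug score.** For patient i and drug d, with f the readout fraction
(HSPC fraction, oncogenic-positive fraction, or any gated population):

    r = 1 − mean(f over drug wells) / mean(f over matched control wells)

pooling all replicates and concentrations (per-concentration scores are
available as diagnostics). Controls are matched by modality: DMSO for small
molecules, PBS for biologics, isotype for antibodies. Significance is a
two-sided pooled-variance Student's t-test on the well-level values; the
signed significance is sign(r)·(−log10 p), positive for on-target depletion.
Degenerate cases: both groups constant with equal means → p = 1; both
constant with different means → p floored at 1e−16 (p stays in (0, 1]);
zero control mean → the response is flagged invalid and excluded from cohort
summaries. p-values are not multiplicity-adjusted at the per-drug level;
Benjamini–Hochberg adjustment is available where analyses call for it.

**Response classes.** responder = p < 0.05 and r > 0; resistant = p < 0.05
and r < 0; everything else non-responder. Treating non-significant
off-target responses as non-responders (rather than resistant) is a
configuration switch (`resistant_requires_significance`).

**Cohort summaries.** Per drug and stratum (e.g. driver mutation): mean
signed significance per readout, and the fraction of patients with a
significant on-target effect averaged across the two readouts. The null
type-I rate of the scoring path is measured on the HSPC readout, counting
all p < 0.05 calls of the two-sided test.

## Proteotype processing

The enforced order is normalize → outlier flags → missingness filter →
imputation → contaminant regression, and each step appends to the matrix's
provenance record.

* **Normalization/summarization** is a documented simplified stand-in for a
  full feature-level mixed model: features are log2-transformed, each
  sample's feature-level median is shifted to the global median, and a
  protein's value is the median of its features. Whether a mixed-model
  summarization would change downstream conclusions is not evaluated here.
* **Outliers** are flagged per cell type by (a) median Pearson correlation
  to same-cell-type samples below median − 3·MAD and (b) missing-value count
  above median + 3·MAD, with the normal-consistent MAD (scale 1.4826).
  Cutoffs are configurable; with fewer than 3 samples no flags are raised.
* **Missingness filter:** a protein is retained iff observed in ≥ 90% of the
  samples of at least one group; the grouping is the five disease×mutation
  groups (HD, ET-CALR, ET-JAK2, MF-CALR, MF-JAK2). The filter is idempotent.
* **Imputation:** each missing value becomes
  log2(2^min_p · (1 + U(0, 0.05))) — the protein's lowest observed value
  plus up to 5% upward noise on the linear scale. Noise direction is upward
  by choice (values at the detection limit are left-censored); observed
  values are never altered, the imputation mask is retained, and the draw is
  deterministic given the seed.
* **Hemoglobin regression:** the covariate is the per-sample mean of the
  HBA/HBB/HBD log2 values; every protein is replaced by its OLS residual
  against the covariate. By default the residual is re-anchored at the
  protein's mean (intercept evaluated at the covariate mean) so fold changes
  keep their scale; a pure-residual mode (zero-centered) is available. After
  the transform every protein's correlation with the covariate is zero to
  numerical precision. Regression runs after imputation (the matrix must be
  complete); a constant covariate degenerates to the identity with a
  warning.
* **Distances:** between-sample Euclidean distances over the full processed
  protein vector, self-pairs excluded, with Student's t-tests between
  selected distance distributions.

## Repeated-RFE signature selection

Each run: a stratified 70/20/10 train/validation/test split; recursive
feature elimination on the training set, dropping 10% of remaining features
per step (floor 1) until 30 remain, with the per-feature importance taken as
the mean absolute multinomial-logistic-regression coefficient over 6
stratified CV folds (an MLP exposes no per-feature importance, so the linear
ranker drives elimination and the MLP is used only for classification); a
small hyperparameter grid for the MLP (hidden layer 32 or 64, L2 penalty
1e−4 or 1e−2) scored on the validation set; the chosen configuration refit
on train+validation and scored once on the test set (accuracy, weighted F1,
macro F1), with 6-fold CV scores of the chosen configuration on the training
set reported alongside. Over n_runs = 100 seeded runs (run seeds derived
from one base seed), per-protein selection frequencies are aggregated and
the signature is the set selected in ≥ 85 runs. Raising the threshold can
only shrink the signature. The end-to-end validation uses a scaled-down mode
of 25 runs with the proportional threshold ceil(0.85·25) = 22, which keeps
the loop to well under a minute per run on one CPU.

## Association statistics and preranked GSEA

**Per-protein ANOVA.** x_p ~ factor (+ confounder) as a linear model; the
factor term is tested by the partial F-test (QR-based, vectorized over
proteins). The sign is the direction of the first factor level versus the
rest (categorical) or the slope after partialling the confounder
(continuous, e.g. VAF with diagnosis as confounder). Signed significance is
sign·(−log10 raw p); BH adjustment is across proteins. A constant factor is
an error; a factor collinear with its confounder yields NA p-values with a
warning.

**Volcano t-tests.** Two-sided pooled-variance t per protein with log2FC =
mean(A) − mean(B); degenerate zero-variance cases follow the same p
convention as the drug score. Results are antisymmetric under group swap.

**Preranked GSEA** is implemented from scratch. The ranking is sorted
descending with ties broken by statistic magnitude then protein ID. The
enrichment score is the maximum deviation of the weighted
Kolmogorov–Smirnov running sum with hit weights |stat|^w (w = 1 by default;
w = 0 gives the unweighted statistic, invariant under monotone transforms of
the ranking). The null permutes gene labels — random same-size sets — rather
than phenotypes, because the input is a preranked statistic; p =
(1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1), which respects the 1/(n_perm+1)
lower bound, and NES = ES / mean |ES_null| of matching sign. Set-size bounds
default to 5–500 after intersection with the ranking.

**Network assembly.** Per factor: the top-20 proteins by adjusted p among
those with adjusted p < 0.001; pathway nodes at adjusted p < 0.05; edge
weights are the signed significances; physical-interaction edges are
restricted to included proteins with score > 0.7.

## Integration

All joins are by patient id; patients missing from one modality are recorded
in the outputs' metadata rather than silently dropped. The drug-response
value for correlation analyses is the signed significance of the on-target
readout. Per drug, Spearman correlations (average-rank ties) of protein
levels against responses feed the preranked GSEA, and significant
enrichments are counted per set across drugs (positive = sensitivity).
Drug–clinical associations reuse the ANOVA engine on the drug×patient
signed-significance matrix, with counts split by the sign of the
association. Responder-proteome analyses compare responders to everyone
else, pooling a drug class by requiring response to ≥ 3 members. The
replicative signature is the top 50 proteins by average (across cell types)
Pearson correlation with the mean MCM4/MCM7 level; patients are ranked by
mean anchor level within each cell type, ranks are averaged across available
cell types, and tertiles define low/medium/high (ties broken by patient id).
VAF correlations are computed within the driver stratum, with a
diagnosis-confounded ANOVA emitted alongside, and proteins at p < 0.01 feed
the network stage. The homozygous drug differential compares mean signed
significances of homozygous-CALR MF patients (VAF ≥ 75%) against
heterozygous-CALR and JAK2 MF references, flagged NA when a group has fewer
than two patients.

## Synthetic-data generator

The generator emulates the structure of an integrated MPN study: a
five-group cohort (defaults 31/21/21/20/20 = 113 patients), log2 proteomes
x[p,s] = baseline + block effects + δ_p·h_s + N(0, σ) per cell type
(granulocyte, HSPC, T-cell), and per-patient pharmacoscopy plates. Blocks
plant group shifts, VAF-proportional slopes (heterozygous VAF ~ U(20, 60);
homozygous MF-CALR VAF ~ U(75, 100) for a configurable fraction, default
0.2), or loadings on one per-patient latent shared across cell types
(MCM-anchored co-regulation). Contamination h_s is lognormal per sample with
loading 1 on HBA/HBB/HBD and configurable bystander loadings, which makes
the regression step testable. Missingness combines per-protein
left-censoring at an empirical detection-limit quantile (default 5%) with
MCAR (default 2%).

Plates follow the study layout: small molecules in duplicate at 1 and 10 µM,
biologics/antibodies in triplicate at 0.1/1/10 µg/ml, 12 DMSO and 6 PBS/
isotype control wells, 25 image sites per well, default 10,000 cells per
well. Channel intensities are lognormal with class-specific modes; the
marker-positivity ground truth is an intensity above a class-independent
threshold placed between the T-cell and HSPC/monocyte modes; per-patient
positive rates scale with VAF. Planted drug effects convert targeted viable
cells (HSPC, marker-positive, or a named class) to dead with probability
1 − survival, optionally restricted to a patient subset (e.g. homozygous
CALR) or modulated by a proteome latent. The intensity distributions and
noise scales are free knobs chosen to be realistic, not estimates from any
dataset. All randomness derives from one root seed through named
SeedSequence spawn-key streams, so outputs are byte-identical given the
seed, and every planted quantity is emitted in a machine-readable truth
record.

What the generator does not emulate: pixel-level images (classification
operates on planted per-cell features, so the classifier's measured accuracy
says nothing about image-analysis performance on microscopy data),
mass-spectrometry acquisition (no peptide-level interference, batch drift or
retention-time structure), clinical outcomes, and cross-feature correlation
beyond the planted blocks. Passing validation therefore demonstrates that
the statistical machinery recovers known structure under the stated noise
model, not that it would perform identically on real cohorts.

## Validation scenarios and problem sizes

The named scenarios (`pharmotype.synth.scenarios`) fix the study conditions
used by the test suite and `scripts/acceptance.py`: a 40-patient × 20-drug
null screen (300 cells/well) for type-I calibration; a 20-patient screen
with one planted survival-0.5 drug (1000 cells/well) for effect recovery; a
43-patient cohort with 3 patients planted below the 0.3% HSPC bar (3000
cells/well) for the QC rule; the 113-sample five-group proteome at 4000
proteins for regression orthogonality; five classes × 20 patients with 15
planted discriminative proteins among 500 for the scaled-down 25-run RFE
recovery; a 50-patient three-cell-type cohort with the planted 50-protein
replicative block; and a 22-patient MF screen with one
homozygous-CALR-specific oncogenic kill. Cell counts per well are kept in
the hundreds-to-thousands in these scenarios — the planted effects and well
replication, not the per-well cell count, carry the signal, and binomial
noise at these counts is already far below the effect sizes tested. MCM
tertile agreement is measured as Kendall τ between assigned categories and
the tertiles of the true latent (perfect agreement → τ = 1).

## Known limitations

The RFE estimator identity, the GSEA permutation scheme and the exact
summarization model are field-standard choices documented above rather than
reproductions of any specific pipeline; alternatives (tree-based RFE
rankers, phenotype permutation, mixed-model summarization) may rank
borderline features differently. Selection frequencies near the 85-run
threshold are sensitive to dataset-level chance correlations: on a fixed
cohort, a noise protein correlated with class labels by chance can be
selected consistently across runs, so the signature threshold separates
planted from noise signal only when the planted effects dominate. The
positivity-threshold policy assumes T-cells are a valid negative reference
and that the target population's median separates from it; cohorts where
the marker-positive fraction is below ~50% in HSPCs/monocytes yield a
conservative (low) threshold and inflated positive fractions, which cancels
in the relative score but matters for absolute positivity estimates.
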