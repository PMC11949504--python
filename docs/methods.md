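# Methods

## The model

The package assumes a cohort of CKD patients measured on a proximity-
extension-assay-style panel: each patient i has an NPX value x_ij per
protein j, already on a log2 scale, with missing entries. The working
hypothesis is that a latent two-state senescence endotype partitions the
cohort, expressed as an additive NPX shift on a small set of
senescence-associated proteins, and that this same axis drives renal
decline: patients with higher expression of those proteins have lower eGFR
at 1-year follow-up. Discovery proceeds in the order QC → imputation →
ranking → panel selection → clustering → characterisation; the pseudobulk
stage is an independent transcriptomic check of the pathway-level signal.

## QC and imputation

A protein is retained only when its observed fraction across patients is
*strictly greater* than 0.8 ("over 80%"), so a protein seen in exactly 80%
of patients is dropped; the boundary is unit-tested on a 79-patient cohort
(63/79 ≈ 0.797 dropped, 64/79 ≈ 0.810 kept). How missingness surviving QC
should be handled before PCA/k-means is an open choice; we median-impute
per protein because PCA and k-means require complete data, medians are
robust on log-scale values, and with ≤20% missingness per retained protein
the median is a stable location estimate. The choice is logged at run time
and isolated in `impute_missing` so other strategies can be swapped in.

## Bootstrap loading-score ranking

Proteins are z-scored before PCA. NPX baselines differ per assay, so
unscaled PCA would rank proteins by variance rather than class signal; a
`scale=False` flag preserves the covariance-PCA alternative. "The PC that
spans the most class variance" is operationalised as the PC (among the
first 10) maximising the one-way ANOVA F of its scores across the
mild/moderate/severe groups, with ties broken toward the lower index; on
data where severity separates along PC1 this reduces to picking PC1.

Each of the 500 bootstraps resamples patients with replacement at full
cohort size, refits the PCA, reselects the PC, and sign-aligns the loading
vector to the full-data reference (PCA loadings are defined up to sign;
without alignment, medians over sign-flipping vectors are biased toward
zero — taking absolute values already protects the ranking metric, the
alignment is belt and braces and is logged). The per-protein median
absolute loading is the ranking metric; ties break lexicographically by
protein id so rankings are reproducible. A bootstrap that draws a
zero-variance sample is redrawn, failing after 10 retries; a resample that
collapses to a single severity class falls back to the full-data PC index.

## Forward panel selection

The panel grows in rank order. At each prefix length the z-scored panel
matrix is clustered with k-means for every k in 2…10 (k-means++
initialisation, best of 25 restarts by inertia, tolerance 1e-6 — restart
count chosen so fixture clusterings are restart-stable), and the prefix
passes when its best-over-k mean silhouette is ≥ 0.5. The returned panel is
the longest passing prefix; the full (step, k) silhouette trace is retained
for plotting. The threshold is checked across all k because the cluster
count should not interfere with feature selection; the per-k trace keeps
the k = 2 slice recoverable. The scan stops after 10 consecutive failing
prefixes: once uninformative proteins are appended, each additional noise
dimension adds the same expected squared distance within and between
clusters, so the silhouette declines monotonically in expectation and
cannot recover. Euclidean distance is used throughout (k-means implies it).

For the final panel, the reported k maximises mean silhouette, with the
Calinski–Harabasz index and the within-cluster sum of squares reported per
k for elbow-style validation. The two clusters are named by mean raw-NPX
over the panel (higher → severe cohort; exact ties break to cluster 0 =
mild, with a warning).

## Differential expression and clinical contrasts

Welch's two-tailed t-test is used throughout because the severe and mild
cohorts have unequal proteomic variance; degrees of freedom follow
Welch–Satterthwaite. When both groups have zero variance the test returns
p = 1 for equal means and p = 0 (with a warning) otherwise. Since NPX is
log2, log2FC = mean(severe) − mean(mild). Multiplicity is controlled with
Benjamini–Hochberg FDR — the omics default where only "adjusted p-value"
is specified. The heatmap export takes the top 25 proteins by p-value
(z-scored per protein, patients blocked by cohort); 25 is an export
default, not an analysis parameter.

eGFR uses the IDMS-traceable re-expressed MDRD constant 175 (the older
constant 186 is switchable via the `constant` argument); creatinine is
converted from µmol/L to mg/dL by dividing by 88.4. KDIGO stages bin eGFR
as G1 ≥ 90, G2 60–89, G3a 45–59, G3b 30–44, G4 15–29, G5 < 15, and severity
groups are mild = stages ≤ 3a, moderate = 3b, severe = 4–5; stage G1 is
grouped with mild (cohorts recruited at stage ≥ 2 make this moot for real
data). Trajectory regressions put NPX on the y axis and log2(follow-up
outcome) on the x axis, matching the published plot orientation; R² is
orientation-invariant, the slope is reported in that frame. Demographic
chi-squared tests omit the Yates correction (the severity tables have
df = 2, where the correction does not apply, and the recomputed published
p-values match only without it). The summary-statistics ANOVA uses the
algebraic identities SSB = Σ nᵢ(x̄ᵢ − x̄)², SSW = Σ (nᵢ−1)sᵢ², so it is
exactly the raw-data one-way ANOVA when given exact summaries (identity
unit-tested to 1e-10).

## Over-representation analysis

The enrichment stage is a plain hypergeometric ORA: for each gene set,
P[X ≥ k] with N = universe size, K = set members in the universe,
n = query size, BH-adjusted across terms, with fold enrichment
(k/n)/(K/N). The universe defaults to the assayed post-QC proteins — the
measured background — not the whole genome. The original analysis used an
active-subnetwork enrichment tool that augments the query with
protein–protein-interaction neighbours before testing; that search needs an
external PPI network and is deliberately out of scope, so published fold
enrichments are not expected to be reproduced numerically.

## Pseudobulk validation

Counts are summed per (sample, cell type), giving each biopsy one datapoint
per cell type. Rows are CPM-normalised; when gene lengths are supplied, TPM
is computed as length-normalised rates rescaled to 1e6 (with equal lengths
TPM ≡ CPM; without lengths the TPM transform falls back to CPM with a
warning — counts alone do not determine TPM, and the choice is a config
flag). Samples with any cell-type row totalling under 50,000 counts are
removed (the source analysis removed three starved biopsies without stating
its threshold; 50,000 is configurable and removals are always logged). DE
runs the same Welch engine as the proteomic stage on log2(TPM+1) per cell
type, BH-adjusted per cell type. Using Welch on log-transformed pseudobulk
rather than a count model (negative-binomial GLM) keeps one DE engine
across modules and is a documented divergence from count-based practice;
with tens of summed cells per row the log-scale normal approximation is
serviceable, and the planted-recovery and null-control tests quantify
exactly what it delivers on the generator.

## The synthetic generators

`generate_cohort` draws per-protein baselines µⱼ ~ Normal(4, 1) NPX
(heterogeneous assay baselines prevent trivially standardised inputs),
assigns each patient to the severe-like endotype with probability 0.4
(default), and shifts the informative proteins by `effect_size` (default
3 NPX ≈ 8-fold) in that endotype over Normal(0, 1) noise. Defaults — 80
patients, 200 proteins, 10 informative, 5% missingness — mirror the scale
of the discovery cohort. Senescence labels cover informative proteins with
probability 0.8 and background proteins with probability 0.25. Renal
coupling is log2(eGFR_fu) = a − s·(mean informative NPX) + Normal(0, 0.15)
with s = `trajectory_slope` (default 0.75; with the default effect size the
squared correlation between an informative protein and log2 follow-up eGFR
is then ≈ 0.64 in expectation, comfortably above the R² = 0.5 property
being tested, while keeping follow-up eGFR in a clinically plausible 10–90
range). Baseline eGFR uses a gentler coupling (slope 0.5, noise 0.35) so
KDIGO stages spread across mild/moderate/severe; creatinine is obtained by
inverting the MDRD equation, making eGFR, creatinine, age and sex mutually
consistent; severe-like patients are drawn older (66 ± 10 vs 55 ± 13
years). Everything is reproducible from a single seed.

The generator does *not* emulate realistic proteome covariance (proteins
are conditionally independent given the endotype), batch effects, assay
limits of detection, or longitudinal measurements beyond one follow-up —
so passing recovery tests demonstrate the pipeline's correctness under its
own assumptions, not robustness to correlated backgrounds.

The 16-protein reference fixture (`reference_cohort_spec`) plants 16
informative proteins with effect size 2.6 NPX at mixture weight 0.5. The
values come from the silhouette geometry: for m planted proteins with
effect e and unit noise, the expected panel silhouette of the
all-informative prefix is independent of m, and appending one noise protein
drops it below 0.5 exactly when e² ∈ (6, 7.03); 2.6² = 6.76 sits mid-band,
so the forward selection's threshold crossing lands at the 16 planted
proteins. The fixture uses 400 patients to keep the crossing sharp against
sampling noise. It is a synthetic stand-in for the undeposited discovery
cohort, not a reconstruction of it.

`generate_counts` draws cell × gene counts from a Gamma–Poisson (negative
binomial, dispersion 0.1) model with log-normal gene abundances (σ = 1.2),
per-cell-type abundance modulation (σ = 1 on log2, the "cell-type
structure"), per-sample biological noise (σ = 0.25 log2), and per-cell
library sizes stretched to span a guaranteed ≥ 4-fold range. Injured
("case") samples multiply the planted DE genes by 2^lfc before per-cell
renormalisation, so library sizes are preserved and a mild compositional
shift of non-DE genes — as in real sequencing — is included. Defaults (12
samples, 6 vs 6, 1000 genes, 50 DE genes at lfc = 2, 120 cells/sample,
mean depth 2000) are sized for the validation experiments.

## Numerical choices and degenerate inputs

Zero-variance proteins z-score to zero columns and rank last with zero
loading. `select_pc` requires at least two severity classes with ≥ 2
patients each, returns PC1 with a warning when labels are absent, and
breaks F ties toward the lower PC. Silhouette requires ≥ 2 clusters and
scores singletons 0; Calinski–Harabasz is undefined at n = k. Welch df
falls back to n₁+n₂−2 if the Satterthwaite ratio underflows. BH adjustment
enforces monotonicity via the step-up running minimum. All stochastic
stages accept explicit seeds; the pipeline expands one root seed into
per-stage seeds recorded in the run manifest.

## Problem sizes in the validation experiments

The recovery experiments run 20 cohorts of 80 patients × 200 proteins with
500 bootstraps each; null DE control uses 10 cohorts; pseudobulk recovery
uses 10 count draws of 12 samples × 1000 genes × ~120 cells/sample. These
sizes make the full validation suite run in minutes on a single CPU while
leaving the statistical margins (≥ 18/20 successes, ≤ 7% false positives,
≥ 60% median recovery) far from their failure boundaries.

## Known limitations

* The ORA stage will not reproduce PPI-augmented enrichment statistics.
* Welch-on-log2(TPM+1) pseudobulk DE is less powerful than count-model DE
  at very low expression; genes detectable only through a count likelihood
  may be missed.
* The silhouette threshold of 0.5 is a convention; on data where no prefix
  reaches it the selection fails loudly rather than returning a weak panel.
* Case-sensitive symbol matching between NPX proteins, senescence labels
  and GMT members is the default; a case-folding join is available but
  heterogeneous identifier schemes (UniProt vs HGNC) are the caller's
  responsibility.
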