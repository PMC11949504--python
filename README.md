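# sendotype

Senescence-endotype ("sendotype") discovery from plasma proteomics, for
researchers studying chronic kidney disease (CKD) progression. Given a wide
NPX matrix (patients × proteins, Olink-style log2-scale expression), a
clinical table with baseline and 1-year follow-up renal metrics, and a list
of senescence-associated protein symbols, the package:

1. **filters** proteins by completeness (kept only if observed in >80% of
   patients) and median-imputes the remainder;
2. **ranks** proteins by bootstrapped PCA loading magnitude — patients are
   resampled with replacement (n = 500), a PCA is fitted per bootstrap, the
   principal component spanning the most severity-class variance is selected
   (max one-way ANOVA F of the PC scores), loading vectors are sign-aligned
   to the full-data reference, and proteins are ordered by the median
   absolute loading |ℓ̃ⱼ| across bootstraps;
3. **selects a minimal panel** by forward feature selection over the ranked
   list: at each step k-means (k = 2…10) is run on the z-scored candidate
   panel and the panel retained is the longest prefix whose best-over-k mean
   silhouette s̄ = mean((b−a)/max(a,b)) stays ≥ 0.5; cluster count is chosen
   by silhouette, cross-checked with the Calinski–Harabasz index
   (SSB/(k−1))/(SSW/(n−k)) and the within-cluster-SS elbow;
4. **endotypes** patients with k-means on the panel, naming the cluster with
   higher mean panel NPX the severe cohort;
5. **characterises** the endotypes: per-protein Welch two-tailed t-tests
   (NPX is log2, so the mean difference *is* the log2 fold change) with
   Benjamini–Hochberg adjustment; clinical contrasts (age, urea, eGFR,
   creatinine, follow-ups); per-protein OLS regressions of NPX against
   log2(follow-up eGFR/creatinine); MDRD eGFR
   (175·(Scr/88.4)^−1.154·age^−0.203·0.742^female·1.212^black) and KDIGO
   staging; and hypergeometric over-representation of significant symbols
   against user-supplied GMT gene sets;
6. **validates** pathway-level signal in single-cell transcriptomics by
   cell-type pseudobulk aggregation (summed counts per sample × cell type),
   CPM/TPM normalisation, low-expression sample removal, and Welch DE on
   log2(TPM+1).

Because the original patient cohort is not deposited, the package ships a
synthetic-cohort generator (`sendotype.synthetic_data`) that reproduces the
structure the analysis assumes — two latent endotypes separated on a small
senescence panel, clinical follow-ups inversely coupled to those proteins,
and cell-type-structured negative-binomial counts with a planted injury
signature — plus the published demographic summary tables, so every stage is
testable offline.

## Worked example

```python
from sendotype import (CohortSpec, DiscoveryConfig, generate_cohort, run_discover)

npx, clinical, labels, truth = generate_cohort(CohortSpec(seed=123))
result = run_discover(npx, clinical, labels,
                      config=DiscoveryConfig(seed=123), out_dir="run")
print(result.summary["panel_size"], result.summary["chosen_k"],
      result.summary["cohort_sizes"])
print(result.clinical_contrasts[["mean_severe", "mean_mild", "direction"]])
```

prints

```
11 2 {'mild-cluster': 48, 'severe-cluster': 32}
                     mean_severe   mean_mild         direction
variable
age                    68.423347   56.086691  higher_in_severe
urea                   13.724796    6.699989  higher_in_severe
egfr_baseline          25.094532   62.774023   lower_in_severe
egfr_followup          14.331865   66.051834   lower_in_severe
creatinine_baseline   218.200761  104.115354  higher_in_severe
creatinine_followup   351.437515   98.131653  higher_in_severe
```

The 80-patient cohort hides a 10-protein signature (3 NPX shift, unit
noise); the pipeline recovers an 11-protein panel containing all 10 planted
proteins at k = 2, and the severe cluster (32 patients) shows the expected
clinical profile — older, higher urea and creatinine, lower baseline and
follow-up eGFR. The same run writes volcano/heatmap-ready CSVs, trajectory
regressions and a reproducibility manifest into `run/`.

A shell entry point mirrors the library:

```bash
sendotype simulate cohort --seed 123 --out-dir sim
sendotype discover --npx sim/npx.tsv --clinical sim/clinical.csv \
    --labels sim/senescence_labels.txt --seed 123 --out-dir run
```

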