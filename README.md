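# mirsig

Serum circulating-miRNA (c-miRNA) signature discovery for
pancreatobiliary cancer (PBca) screening — the full computation from raw
microarray signals to a validated multi-miRNA diagnostic index, built
for researchers developing blood-based cancer biomarkers against the
clinical standard CA19-9 (positivity cutoff 37 U/mL).

## What it computes

Starting from probe × sample microarray signals with target /
negative-control / internal-control annotation and clinical metadata,
the pipeline runs:

1. **Preprocessing** — per-sample positive-call thresholds
   (mean + 2·SD of trimmed negative controls), within-set mean
   imputation, and normalization of each log2 signal by the per-sample
   mean of three internal-control miRNAs (Int-con), a proxy for total
   serum miRNA concentration.
2. **Robustness filter** — keep miRNAs with call rate > 90% whose log2
   signal regresses on Int-con with Pearson rsq > 0.5 in two
   independent healthy cohorts and a between-cohort slope difference
   < 0.1.
3. **Coexpression modules** — unsigned weighted network
   (|cor|^5), topological overlap, average-linkage clustering with a
   dynamic tree cut (min module size 10, deep split 3), module
   eigengenes, and Pearson module–trait analysis; modules driven more by
   serum storage time (a pre-analytic disturbance) than by any disease
   trait are rejected, the rest with a significant disease-trait
   association contribute their members as disease-related miRNAs.
4. **Ridge marker ranking** — an L2-penalized linear-discriminant fit of
   disease status on all disease-related miRNAs (10-fold CV over a
   lambda grid); the 16 largest absolute coefficients become the
   diagnostic markers.
5. **Signature search** — Fisher LDA
   `w = S_pooled⁻¹(μ_case − μ_control)` on **every** 5-of-16 marker
   subset, three decision constants per subset (maximum separation,
   80%-sensitivity, 80%-specificity): 3 × C(16,5) = 13,104 candidate
   discriminants, each scored by 5-fold × 10-repeat (50-group)
   cross-validation. Selected signatures must exceed 80% mean
   sensitivity and specificity, have an AUC 95% CI lower bound ≥ 0.80,
   and beat CA19-9's AUC on the same folds.
6. **Evaluation** — Mann–Whitney AUC with DeLong CIs and paired DeLong
   comparisons, classification tables including the combined rule
   (index > 0 OR CA19-9 ≥ 37 U/mL), and subgroup analyses (cT stage,
   CA19-9 strata) against the shared healthy control set.

A first-class synthetic cohort generator
(`mirsig.synthetic_data`) emulates the statistical structure each stage
assumes — a shared concentration factor tracked by internal controls,
block-correlated miRNA modules, up- and down-regulated disease modules,
a storage-time degradation module, censoring, and disease-linked
clinical traits — so the whole pipeline is exercised end-to-end with no
external data. `docs/methods.md` describes the model and every default.

## Worked example

```python
from mirsig.pipeline import run_pipeline
from mirsig.synthetic_data import SyntheticConfig

result = run_pipeline(SyntheticConfig(seed=1), with_search=True, with_validation=True)
print(result.recovery)
report = result.validation_report
print(f"validation AUC {report.auc:.3f} CI ({report.auc_ci[0]:.3f}, {report.auc_ci[1]:.3f})")
print(report.classification.round(3))
```

prints (a few seconds on one CPU):

```
{'n_robust': 551, 'module_agreement': 1.0, 'disease_modules_flagged': True,
 'disturbance_module_rejected': True, 'top_k_planted_fraction': 1.0,
 'n_selected_discriminants': 4271, 'best_auc_mean': 0.9263,
 'best_auc_ci_low': 0.9184, 'ca199_cv_auc': 0.8618}
validation AUC 0.904 CI (0.845, 0.964)
          sensitivity  specificity    tp    fn    fp    tn
index           0.851          0.8  40.0   7.0  10.0  40.0
ca199           0.596          0.9  28.0  19.0   5.0  45.0
combined        0.936          0.7  44.0   3.0  15.0  35.0
```

Reading this: of 600 synthetic miRNAs, 551 pass the robustness filter;
the planted module partition is recovered exactly; both planted disease
modules are flagged and the storage-disturbance module is rejected; all
16 ridge-selected markers carry a planted disease effect; 4271 of the
13,104 discriminants pass the selection criteria, and the best one
cross-validates at AUC 0.926 versus 0.862 for the synthetic CA19-9
trait. On the independent synthetic validation set the refit signature
scores AUC 0.904, and the OR-combination with CA19-9 raises sensitivity
(0.851 → 0.936) at the usual cost in specificity.

The same stages are available from the shell via the `mirsig` command
(`simulate`, `preprocess`, `robust`, `modules`, `rank`, `search`,
`evaluate`, `qc-timecourse`, `qc-embed`), reading and writing plain
TSV/CSV/JSON.

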