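# radcascade

Preoperative CT-radiomics classification of pediatric neuroblastic tumors.

Neuroblastic tumors span three pathological types with very different
prognosis and treatment: benign **ganglioneuroma (GN)**, intermediate
**ganglioneuroblastoma (GNB)**, and malignant **neuroblastoma (NB)**. Typing
currently requires biopsy. `radcascade` implements, as a tested and reusable
Python pipeline, a radiomics approach that types the tumor from a
contrast-enhanced CT volume and its segmentation mask:

1. **Harmonize** — resample image + mask to 0.5 × 0.5 × 5 mm; re-bin gray
   levels with a fixed bin width of 20.
2. **Extract** — 851 radiomic features per ROI: 14 shape, 18 first-order,
   75 texture (GLCM/GLRLM/GLSZM/GLDM/NGTDM), and first-order + texture on 8
   undecimated wavelet sub-bands (107 + 8 × 93).
3. **Select** — stratified 3:1 train/validation split; per-feature screening
   across the three types (ANOVA when all classes pass Shapiro–Wilk,
   Kruskal–Wallis otherwise, keep p < 0.05); maximum-relevance–minimum-
   redundancy (mRMR) ranking of survivors + age + gender; keep the top 10.
4. **Classify** — a two-stage LASSO cascade: first GN vs non-GN, then
   GNB vs NB, each an L1-penalized least-squares model on a 0/1 response
   with λ chosen by minimum 5-fold cross-validated MSE,

   β̂ = argmin (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁,

   with robust per-stage feature normalization and a Youden-J training
   threshold. A clinical-only baseline (age + gender) is fitted alongside.
5. **Evaluate** — per-stage sensitivity/specificity/AUC (Mann–Whitney), 3×3
   confusion matrix, per-class and overall accuracy, on both splits.

Because the original patient cohort is not public, the package ships a
synthetic cohort generator that produces CT-like ellipsoidal tumors whose
within-mask texture (spatial correlation length, heterogeneity amplitude)
and age distribution differ by class, so the full pipeline is exercised and
class separability is recoverable by construction. See `docs/methods.md` for
the model details and conventions.

## Worked example

```python
from radcascade import (CohortSpec, PipelineConfig, cohort_to_feature_table,
                        sample_cohort, run_from_table)
from radcascade.evaluation import format_metrics_table

spec = CohortSpec(n_per_class=(20, 30, 80), seed=11)      # GN, GNB, NB
table = cohort_to_feature_table(sample_cohort(spec))       # 130 x 854
result = run_from_table(table, PipelineConfig(seed=11))

print([n for n, _ in result["selection"].ranked][:3])
print(format_metrics_table(result["reports"]["clinical_radiomic"]["validation"]))
print(format_metrics_table(result["reports"]["clinical"]["validation"]))
```

prints (exactly, for this seed):

```
['original_glcm_InverseVariance', 'original_firstorder_MeanAbsoluteDeviation', 'original_glrlm_LongRunLowGrayLevelEmphasis']
GN vs non-GN: accuracy 100.0%  sensitivity 100.0%  specificity 100.0%  AUC 1.000
GNB vs NB: accuracy 100.0%  sensitivity 100.0%  specificity 100.0%  AUC 1.000
overall accuracy 100.0%
GN vs non-GN: accuracy 81.8%  sensitivity 0.0%  specificity 96.4%  AUC 0.536
GNB vs NB: accuracy 60.7%  sensitivity 50.0%  specificity 65.0%  AUC 0.662
overall accuracy 48.5%
```

The mRMR ranking lands on GLCM/wavelet texture features (the generator
plants its class signal in exactly those families), the clinical-radiomic
cascade separates the planted classes almost perfectly on the held-out
validation subjects, and the age-and-gender-only baseline does much worse —
the qualitative radiomics ≫ clinical ordering the method is designed to
demonstrate. On real cohorts, absolute numbers will be far lower; the
synthetic cohort measures pipeline correctness, not clinical performance.

A command-line interface mirrors the library
(`radcascade run-all | generate | extract | select | fit | evaluate`, YAML
config, CSV/JSON outputs).

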