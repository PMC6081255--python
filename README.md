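# plaque-radiomics

Radiomic texture analysis of basilar-artery atherosclerotic plaque on
high-resolution vessel-wall MRI (HR-MRI), for researchers studying
intracranial atherosclerotic disease (ICAD) and image-based stroke-risk
markers. The package asks: given a plaque cross-section imaged at T1, T2 and
contrast-enhanced T1, can quantitative features separate acute/sub-acute
symptomatic from asymptomatic plaque better than the conventional
radiological read?

It implements, natively and end-to-end:

* **conventional plaque metrics** — plaque burden `(1 − A_lumen/A_outer)·100%`,
  minimal luminal area (MLA), WASID-style stenosis `(1 − √(A_sten/A_ref))·100%`,
  intraplaque haemorrhage (IPH, the >150%-of-muscle T1 signal rule) and the
  grey-matter-normalised enhancement ratio
  `((S_plaque^post/S_GM^post)/(S_plaque^pre/S_GM^pre) − 1)·100%`;
* **a from-scratch 2D radiomic engine** — 98 named features per sequence:
  first-order statistics, shape, and GLCM / GLRLM / GLSZM texture matrices
  over a 32-level equal-width discretisation (distance 1, four directions,
  direction-averaged);
* **statistics** — t-tests and chi-squared screening, stepwise logistic
  regression with odds ratios, Mann–Whitney AUC, Youden operating points with
  likelihood ratios, and the DeLong test for correlated AUCs;
* **a native random forest** — ten bootstrap-sampled, feature-subsampled
  Gini trees of depth 3 with averaged leaf probabilities, fully
  deterministic given a seed;
* **inter-reader agreement** — ICC(2,1) (two-way random, absolute
  agreement), Bland–Altman limits, Cohen's kappa;
* **a synthetic plaque-image cohort generator** that reproduces the study's
  group structure (61 symptomatic / 35 asymptomatic; IPH 19/61 vs 1/35; MLA
  3.78±2.80 vs 2.39±1.46 mm²; enhancement 24.2±29.5 vs 3.4±21.9 %), so the
  whole pipeline can be exercised without patient data.

See `docs/methods.md` for model details and assumptions.

## Worked example

```python
import plaque_radiomics as pr

spec = pr.CohortSpec(seed=7)                 # 61 + 35 synthetic patients
studies = pr.generate_cohort(spec)
table = pr.build_feature_table(studies)      # 96 x (clinical + 3x98 features)
result = pr.full_analysis(table, seed=7)

for name, model in result["models"].items():
    d = model.diagnostic
    print(f"{name:12s} AUC={d.auc:.3f} sens={d.sensitivity:.3f} "
          f"spec={d.specificity:.3f} LR+={d.lr_plus:.2f} cv_auc={model.cv_auc}")
print("DeLong traditional vs radiomic p =",
      round(result["delong"]["traditional_vs_radiomic"]["p"], 4))
```

prints (seed 7):

```
traditional  AUC=0.846 sens=0.803 spec=0.886 LR+=7.03 cv_auc=0.72
radiomic     AUC=0.933 sens=0.934 spec=0.800 LR+=4.67 cv_auc=0.72
combined     AUC=0.929 sens=0.852 spec=0.886 LR+=7.46 cv_auc=0.72
DeLong traditional vs radiomic p = 0.0278
```

The traditional tier (stepwise logistic on IPH, MLA, enhancement ratio and
clinical covariates) separates the groups with an apparent AUC near 0.85;
the radiomic forest on selected T1 + CE-T1 features is significantly better
by the DeLong test; the cross-validated AUCs show how optimistic
resubstitution is at n = 96. On this particular cohort draw the combined
tier lands just below the radiomic tier; across many simulated cohorts the
full ordering traditional < radiomic < combined holds in the large
majority of seeds (see the acceptance script below).

A command-line interface mirrors the workflow:

```bash
plaque-radiomics simulate --out cohort/ --seed 7
plaque-radiomics extract  --manifest cohort/manifest.csv --out features.csv
plaque-radiomics analyze  --features features.csv --out results/ --seed 7
plaque-radiomics report   --results results/results.json
plaque-radiomics agreement --manifest cohort/manifest.csv --subset 40 \
    --jitter 1.0 --seed 7 --out agreement.json
```

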