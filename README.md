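# dgf-kinetics

Analytics for **functional delayed graft function (fDGF)** after
donation-after-circulatory-death (DCD) kidney transplantation.

Recipients of DCD kidneys face severe ischemia-reperfusion injury, and up to
half develop delayed graft function. The dialysis-based DGF definition is
subjective, so the *functional* definition is used instead: fDGF is present
when serum creatinine fails to fall spontaneously by ≥ 10% per day on three
consecutive days during the first post-transplant week, or when dialysis is
required in that week. The second day of the first qualifying three-day run —
the *index day* — dates the resolution of fDGF, giving four severity groups
(< 7, ≥ 7–< 14, ≥ 14–< 21, ≥ 21 days). Resolution can be followed with serial
MAG3 renography via the **tubular function slope (TFS)** — the least-squares
slope of the second (tubular-extraction) phase of the background-subtracted,
dose-adjusted time-activity curve within the first two minutes — but
renography is invasive and costly. Urinary biomarkers of proximal tubular
function (NGAL, B2M and friends) are candidates to replace it.

This package implements the full computational chain for that comparison,
for transplant nephrologists and methodologists who want to reuse or stress
the pipeline:

* `dgf_kinetics.fdgf` — the fDGF classifier on daily creatinine series
  (run detection, index day, duration, severity bins, spontaneity rules for
  dialysis days);
* `dgf_kinetics.renography` — renogram correction
  `y(t) = (g(t) − α·b(t)) / (D·(1−e)·κ)` and the SSE-minimizing two-segment
  linear fit whose second-phase slope is the TFS;
* `dgf_kinetics.biomarkers` — creatinine ratios (U_X/U_cr), the
  protein-to-creatinine ratio, fractional excretions
  `FE_X = 100·(U_X·S_cr)/(S_X·U_cr)`, marker/TIMP2 ratios, endogenous
  creatinine clearance `ECC = (U_cr·V·1000/1440)/S_cr`, and SD
  standardization;
* `dgf_kinetics.stats` — median (IQR) group summaries, logistic odds
  ratios with Wald CIs (Firth penalization opt-in), linear mean differences,
  Pearson correlations with TFS, and Mann–Whitney ROC AUCs
  `AUC = P(X_case > X_control) + ½·P(tie)` with DeLong or stratified
  bootstrap CIs, plus a complete-case sensitivity mode;
* `dgf_kinetics.cohort` — a seeded synthetic cohort generator emulating an
  89-recipient DCD cohort (severity mix 20/20/26/23, severity-dependent
  creatinine recovery, biomarker elevations, TFS ladder, IF/TA prevalence),
  since the original patient-level data are not public;
* `dgf_kinetics.pipeline` / `dgf-kinetics` CLI — the end-to-end run with
  provenance headers and deterministic outputs.

## Worked example

```python
from dgf_kinetics import (CohortConfig, classify, generate_cohort, roc_auc)
from dgf_kinetics.pipeline import cohort_to_table

cohort = generate_cohort(CohortConfig(seed=1))     # default 89-patient profile
rec = cohort[0]
res = classify(rec.creatinine_series)
print(rec.patient_id, res.group, res.resolution_index_day)

table = cohort_to_table(cohort)
for marker in ("ngal_cr", "b2m_cr", "tfs"):
    est = roc_auc(table, marker, pod=4, contrast="fdgf_yes_vs_no")
    lo, hi = est.ci95_display
    print(f"{marker:8s} POD4 AUC {est.auc:.2f} ({lo:.2f}-{hi:.2f})")
```

prints

```
P001 moderate 19
ngal_cr  POD4 AUC 1.00 (1.00-1.00)
b2m_cr   POD4 AUC 0.87 (0.78-0.97)
tfs      POD4 AUC 1.00 (1.00-1.00)
```

i.e. patient `P001` resolved its creatinine plateau on postoperative day 19
(moderate fDGF), and on this synthetic cohort the creatinine-corrected urinary
NGAL at POD 4 discriminates fDGF at least as well as the renography slope,
while B2M trails — the qualitative ordering the pipeline is built to probe.

The same run from a shell:

```sh
dgf-kinetics all --out results/ --seed 1
```

writes the cohort CSVs plus `fdgf.csv`, `tfs.csv`, `derived.csv`, the four
result tables and `correlations.csv`, each with a provenance header.

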