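# Methods

This note documents the models, conventions and calibrations behind
`dgf_kinetics`, the choices made where the underlying clinical definitions
leave room, and what the synthetic-data tests do and do not establish.

## fDGF classification

A day `d` is *qualifying* when the relative creatinine decline
`r_d = (C_{d−1} − C_d)/C_{d−1}` is at least 0.10, both days are observed,
and the decline is spontaneous. fDGF is present when no run of three
consecutive qualifying days has its index day (the run's second day) before
POD 7, or when any dialysis occurs on PODs 1–7. The index day of the first
run over the whole follow-up is the resolution day and the duration; with no
run, the duration is censored at the end of follow-up.

Conventions the functional definition does not fix, and what we chose:

* **Severity bins are half-open**: `[1,7)` no, `[7,14)` mild, `[14,21)`
  moderate, `[21,∞)` severe. The published bin notations are mutually
  consistent only as half-open intervals. A censored duration with
  follow-up ≥ 21 days is severe; follow-up ending before POD 21 without a
  run raises an explicit *indeterminate severity* error rather than a
  silently wrong group.
* **"Spontaneously"**: the default rule disqualifies a day if dialysis
  occurred on it or the previous day, since a creatinine drop across a
  dialysis session says nothing about glomerular filtration. An
  `ignore`-dialysis rule is available for sensitivity analysis.
* **Missing days break runs.** Three successive declines cannot be asserted
  across an unobserved day; a gap therefore delays (never advances) the
  detected resolution.
* **Dialysis-only positives with an early index day.** A patient positive
  solely through the dialysis clause whose creatinine-derived index day
  falls before POD 7 sits outside the definition's own bins (positive, yet
  duration in the "no" bin). We group such patients as *mild* — the
  smallest positive bin — while `duration_days` keeps the creatinine-rule
  value and `by_dialysis` records the cause.
* **Index-day counting** uses calendar PODs (the POD of the run's second
  qualifying decline day), so a run on declines 2–4 has index day 3.

The classifier is checked exhaustively against an independent brute-force
run detector on all 2^13 qualifying patterns of a 14-day window, and
property-tested for scale invariance and monotonicity (an extra qualifying
day can never lengthen the duration).

## Renogram correction and the tubular function slope

Acquisition follows the standard MAG3 protocol: a 100 MBq bolus, frames at
1-second intervals for 120 frames then 20-second intervals for 90 frames.
Counts are converted to rates (counts/s) so both frame regimes are
commensurate, the background ROI rate is subtracted scaled by the ROI area
ratio α (1 when unknown), and the result is divided by the effective dose:

    y(t) = (g(t)/Δt − α·b(t)/Δt) / (D · (1 − e) · κ)

with `D` the injected dose (MBq), `e` the extravasated fraction and `κ` the
camera calibration in counts/s per MBq (default 1 for raw data, making the
formula the plain dose adjustment). Negative corrected values are retained.

**Two-segment fit.** Within the 0–120 s window (1-second frames only), the
fit scans every frame-grid breakpoint leaving at least three frames per
segment, fits an independent least-squares line to each side, and keeps the
breakpoint minimizing total SSE (earliest on ties). The second segment's
slope is the TFS. We deliberately fit the segments *without* a continuity
constraint: each candidate's segment slopes then equal closed-form
simple-regression slopes, which makes the fit verifiable against an
exhaustive oracle, and for a truly piecewise-linear (continuous) curve the
unconstrained fit recovers the same slopes exactly. A fixed-breakpoint mode
supports sensitivity analyses where an operator pins the phase boundary.

**Units.** TFS values are reported in *slope units*, defined as 10⁻³ of the
corrected ordinate per second, calibrated so that the simulator's group
means land on the published magnitude ladder (0.9–2.5). This is a package
convention, not a reconstruction of the original analysis software.

**Count scale.** The simulator's default calibration `κ = 25` counts/s/MBq
puts the graft ROI near 10³ counts/s at two minutes for a 100 MBq bolus — a
plausible large-field-of-view camera rate. At that scale the Poisson
Monte-Carlo bias of the recovered slope is ≲ 1% across the ladder
(500 replicates per slope); at unrealistically sparse counts the free
breakpoint wanders into the steep perfusion phase and biases the slope
upward, which is why the dose-ladder property (bias → 0 as dose → ∞) is
tested at κ = 1.

## Biomarker derivations

Unit canon: analytes in µg/L; creatinine in µmol/L with ratios per mmol
creatinine; total protein in g/L; 24-h volume in litres; FE in percent; ECC
in mL/min.

* `FE_X = 100 · (U_X · S_cr) / (S_X · U_cr)` — computed like the fractional
  excretion of sodium; requires a same-day urine/serum pair and reports
  missing otherwise (never zero).
* `marker-CR = U_X / U_cr` and `PCR = U_TP / U_cr` — dilution corrections;
  both are invariant under simultaneous scaling of all urine
  concentrations.
* `B2M/TIMP2` and `NGAL/TIMP2` use same-sample urine concentrations (TIMP2
  as an alternative filtration denominator); IGFBP7-denominated ratios are
  derivable but not emitted by default.
* `ECC = (U_cr · V · 1000/1440) / S_cr` from the 24-h collection.
* **SD standardization** divides by the sample SD (denominator n−1) over
  non-missing values of that quantity at that POD, cohort-wide; the
  complete-case mode recomputes nothing downstream that depends on it,
  because Pearson correlations and rank-based AUCs are scale-invariant — a
  fact asserted explicitly in the tests.

No derived quantity is produced from partially missing inputs.

## Statistics

* **Group summaries**: median and quartiles with the linear-interpolation
  quantile convention (stated because median (IQR) tables depend on it);
  empty groups are reported missing, not raised.
* **Odds ratios**: maximum-likelihood logistic regression with indicator
  coding; `OR = exp(β)` with Wald 95% CI `exp(β ± 1.96·SE)`; listwise
  deletion and `n_used` reported. On a 2×2 table this reproduces the
  cross-product OR and its textbook CI to 1e-6. Perfect or quasi-separation
  raises a diagnostic instead of silently falling back; a Jeffreys-penalized
  (Firth) fit is available as an explicit opt-in and is always finite.
* **Mean differences**: OLS with indicator coding and t-based CIs,
  equivalent to the two-sample t-test for a two-level exposure.
* **Pearson correlations** on pairwise-complete pairs, two-sided p from the
  t transform; ≥ 3 pairs and non-degenerate variance required.
* **ROC AUC**: Mann–Whitney concordance with half-credit for ties, via
  midranks. Orientation is fixed so a higher marker predicts fDGF, with TFS
  auto-negated (lower tubular extraction ⇒ worse function). Presence
  contrasts use PODs 1 and 4; the severity contrast (POD 10) compares
  severe against mild–moderate, excluding patients without fDGF. CIs by
  DeLong (default) or seeded stratified bootstrap (2000 resamples by
  default); display bounds are truncated to [0,1] while raw bounds are kept
  in machine output.
* **Complete case**: retains patients complete on all ROC markers plus TFS
  at PODs 4 and 10 (the declared analysis set; the original set's exact
  composition is not recoverable from the publication).

## Synthetic cohort generator

The generator exists so every stage is testable without the (non-public)
patient data. Defaults encode the study profile and were fixed once:

* n = 89, severity mix 20/20/26/23 (the exact counts behind the rounded
  22/22/29/26%, which do not sum to 100).
* **Creatinine trajectories** make the intended group a construction
  invariant: the start value is uniform on 500–900 µmol/L; before the
  resolution run the daily multiplicative drift `exp(N(0, σ))` (σ = 0.04)
  is truncated to [0.92, 1.12], so no pre-run day can qualify; from the run
  start the daily decline is at least the recovery rate (15%) until a
  110 µmol/L floor, after which creatinine plateaus. Severe patients are
  censored (no run within the 28-day follow-up) with probability 0.35,
  otherwise resolve on PODs 21–27.
* **Dialysis** is assigned to moderate/severe patients on alternating days
  with creatinine above 500 µmol/L, but never inside the run's spontaneity
  window, so the duration always derives from the creatinine rule while the
  dialysis clause still gets exercised.
* **Biomarkers** are log-normal (log-SD 0.6; half that for creatinine,
  volume, protein and serum analytes) around per-analyte × POD × group
  medians chosen for the published qualitative pattern: urinary NGAL
  separates fDGF from no-fDGF by orders of magnitude at PODs 1/4 and tracks
  resolution; B2M is elevated in all groups early (surgery raises serum
  B2M) with modest separation; urinary creatinine and 24-h volume recover
  fastest without fDGF.
* **TFS** group means: POD 10 uses the published ladder 2.5/1.9/1.0/0.9
  slope units; PODs 1 and 4 use invented ladders (2.0/1.0/0.8/0.6 and
  2.3/1.1/0.85/0.6) preserving the ordering with a wider early gap.
  Renograms are simulated from these per-patient slopes (SD 0.35, floored
  at 0.05) with Poisson counting noise, and the pipeline re-estimates TFS
  by fitting — there is no shortcut from the generator to the analysis.
* **IF/TA** follows a logistic model with a 13% baseline in the no-fDGF
  group and log-odds shifts log(1.9) (mild/moderate) and log(15) (severe),
  i.e. the published OR magnitudes in expectation. KDRI categories are
  drawn from the per-group frequency table; ECC at 6 weeks/12 months is
  Gaussian per group (SD 12 mL/min, floored at 1).
* **Missingness is MCAR**, applied independently per field after
  construction (panel 12%, renogram 8%, biopsy 28%, ECC 8–10%). The real
  cohort's missingness is partly anuria-driven (informative); MCAR is a
  stated simplification, so complete-case comparisons here only exercise
  the machinery, not the bias structure of the original data.

What the generator does **not** emulate: pharmacokinetic creatinine
dynamics, treatment-arm effects, center effects, correlated multi-marker
noise, or informative missingness. Tests passing on this cohort show the
pipeline's arithmetic and its qualitative-structure recovery, not clinical
performance on real patients.

## Numerical choices

* Quantiles: linear interpolation. Standardization SD: ddof = 1.
* Two-segment fit ties break to the earliest breakpoint; segments share no
  frames (first segment ends strictly before the breakpoint frame).
* CSV I/O writes floats with `%.17g` and reads with round-trip parsing, so
  cohorts survive the file round trip bit-exactly; empty cell = missing.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical configuration ⇒ byte-identical outputs
  (provenance headers hash the analysis-relevant configuration only, not
  paths).
* Logistic fits use Newton iterations to gradient tolerance 1e-10;
  non-convergence or |β| > 15 is reported as separation.

## Known limitations

* The severity grouping of dialysis-only positives with sub-7-day
  creatinine resolution is a package convention (see above); such patients
  are rare and flagged.
* DeLong CIs are Wald-type and degenerate at AUC = 1 (zero width); the
  bootstrap option behaves better near the boundary but is still optimistic
  there.
* The TFS "slope unit" calibration and camera sensitivity are conventions;
  absolute slope values are comparable within this package, not across
  devices.
* Problem sizes in the test suite (e.g. 500 Monte-Carlo replicates per
  slope, 20 seeded cohorts, 1000-patient round trips) were chosen as the
  smallest sizes at which the checked statistics are stable.
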