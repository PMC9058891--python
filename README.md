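# tie2response

Vascular response and progression calling from longitudinal plasma Tie2
trajectories, for trials that add a VEGF-pathway inhibitor (VEGFi) to
cytotoxic chemotherapy.

Anti-angiogenic drugs lack a validated response biomarker: radiology reports
the tumour's epithelial bulk, not its vasculature. Plasma Tie2 (pTie2), the
endothelial angiopoietin receptor, falls when a VEGFi is biologically
active. This package turns serial pTie2 (and an epithelial companion marker
such as CK18 or CA125) into decision-ready calls:

* **Vascular response.** Each patient's nine-week change is summarised as
  `x = log2(c(63 d) / baseline)`, with the baseline the geometric mean of the
  pre-treatment draws. Treated-arm changes are deconvoluted by EM into a
  two-component Gaussian mixture — a *responder* component and a
  *placebo-like* component matching the chemotherapy-only distribution
  N(0.16, 0.28²) in log2 units. The two-sided 95% bounds of the components
  set the cutpoints:

  ```
  vCR:  2^x − 1  ≤  2^(μ_p − z·σ_p) − 1      (≈ −24% with μ_p=0.16, σ_p=0.28)
  vNR:  2^x − 1  ≥  2^(μ_r + z·σ_r) − 1      (≈ +7%  with μ_r=−0.55, σ_r=0.33)
  vPR:  otherwise
  ```

  with `z = Φ⁻¹(0.975)`. Thresholds can equivalently be anchored on the
  placebo arm's empirical moments (`threshold_source="placebo_arm"`), which
  is the robust choice at typical trial sizes.
* **Vascular/epithelial progression.** A marker-defined progression event
  triggers at the first visit whose concentration reaches
  `(1 + r) ×` the running nadir of all strictly earlier measurements
  (r = 0.40 for Tie2, 0.50 for CK18). Marker calls combine by OR, and
  detection fractions are evaluated at fixed leads (6 and 12 weeks) before
  the radiological progression day, with an exact McNemar test for the
  added value of the combination.
* **Outcomes and design.** Cox hazard ratios with a scaled-Schoenfeld
  proportional-hazards check and an automatic restricted-mean-survival-time
  (RMST) ratio fallback; median-dichotomised chi-square baseline
  associations; and Schoenfeld's log-rank events formula for sizing a
  response-stratified phase II trial.
* **Synthetic cohorts.** A generator reproduces the assumed data structure
  (mixture-distributed changes, post-nadir exponential rises planted at a
  known lead before radiological progression, class-linked survival) with
  full ground-truth labels for recovery testing.

## Worked example

```bash
tie2response simulate --n 120 --seed 7 --out demo
tie2response classify --measurements demo/measurements.csv \
    --patients demo/patients.csv --seed 7 --threshold-source placebo_arm \
    --out demo/cls
```

```
thresholds (placebo_arm): vCR <= -32%, vNR >= +7%
   category  count   percent
        vCR     17 26.984127
        vPR     29 46.031746
        vNR     17 26.984127
unevaluable      0       NaN
```

The placebo-arm changes of this simulated trial have mean 0.16 and SD ≈ 0.33
in log2 units (the generating 0.28 widened by 10% measurement noise), so the
lower 95% bound lands at a 32% reduction: 17 of 63 treated patients (27%)
are complete vascular responders. Running the full pipeline
(`tie2response run --config run.yaml`, or `run_pipeline` from Python) adds
progression and lead-time stages:

```
 lead_days marker_set  n_progressors  detected  fraction
        42   vascular             93      73.0  0.784946
        42 epithelial             93      58.0  0.623656
        42   combined             93      86.0  0.924731
        84   vascular             93      48.0  0.516129
        84 epithelial             93      40.0  0.430108
        84   combined             93      60.0  0.645161
```

Six weeks before radiological progression, the combined vascular+epithelial
call already flags 92% of the 93 progressors in this cohort, more than
either marker alone — the OR-combination is never worse than its parts. A
design calculation for a follow-up trial:

```bash
$ tie2response samplesize --prevalence 0.4 --hr 0.5
events required: 68.1
patients required: 85
```

i.e. with a 40% responder prevalence, a PFS hazard ratio of 0.5 between
responders and non-responders, two-sided α = 0.05, 80% power and 80% of
patients eventing, 85 patients suffice.

## Library surface

`VascularResponseClassifier` is a scikit-learn-style estimator
(`fit(log2_changes)` → fitted `mixture_` and `thresholds_`;
`predict(log2_changes)` → categories) that composes with sklearn tooling.
Everything else is plain functions over pandas DataFrames and small frozen
dataclasses: `fit_two_component_mixture`, `derive_thresholds`,
`classify_cohort`, `detect_marker_progression`, `lead_time_detection`,
`cox_hr`, `rmst_ratio`, `schoenfeld_sample_size`, `simulate_cohort`,
`run_pipeline`. See `docs/methods.md` for the statistical details and
design choices.

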