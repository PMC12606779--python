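# fragscore

A pipeline for a qPCR-based cell-free DNA (cfDNA) fragmentomic assay that
monitors treatment response in stage IV cancer patients: from raw plate
exports through QC gating and absolute quantification to a calibrated
0–100 **Progression Score (PS)** and a progression / likely-non-progression
call.

## Who this is for

Biostatisticians and assay developers working on liquid-biopsy therapy
monitoring. The package covers the full analysis path — qPCR standard-curve
quantification, eligibility gating, fragmentomic feature derivation,
pre-defined logistic model selection with leave-one-out cross-validation
(LOOCV), and bootstrap calibration of a high-PPV decision threshold — plus a
synthetic-cohort generator so every stage is testable without patient data.

## The assay and the model

Two blood draws are taken per patient (baseline, and 12–21 days after the
first treatment cycle). Multiplex qPCR against high-copy retrotransposon
targets measures, per draw, the plasma concentration of cfDNA longer than
80 bp (short marker, `SM`, an 80 bp ALU amplicon) and longer than 105 bp
(mid marker, `MM`, a 105 bp ALU amplicon). Since an amplicon of length *L*
amplifies only templates ≥ *L* bp, the difference isolates the 80–105 bp
band in which tumor-derived fragments are enriched:

```
Frag1    = max(SM1 − MM1, 0)        short-fragment excess, draw 1
Frag2    = max(SM2 − MM2, 0)        short-fragment excess, draw 2
FragDiff = Frag2 − Frag1            change in tumor-burden signal
MMDiff   = MM2 − MM1                change in background cfDNA
```

White-blood-cell lysis during transport adds genomic DNA to both size
classes roughly equally, so the subtraction cancels it — the mechanism that
keeps shipping artifacts from mimicking progression.

Six pre-defined logistic regressions over subsets of
{`FragDiff`, `Frag1`, `SM1`, `MMDiff`} predict imaging-confirmed progression
(≥ 20 % increase in the sum of target-lesion diameters, RECIST-style). The
preferred model is chosen by training AUC (with a parsimony rule when an
added predictor is not significant), validated by LOOCV, and its predicted
probability is scaled to the 0–100 PS. The call threshold is calibrated by
a 1000-iteration bootstrap: at each candidate threshold the expected
positive predictive value (PPV) is estimated by refitting the model on
resamples, and the smallest threshold whose expected PPV stays ≥ 99 % is
selected — prioritizing specificity so that a progression call is very
rarely wrong.

## Worked example

```python
import fragscore as fs

records, profiles, truth = fs.generate_cohort(fs.ScenarioConfig(seed=7))
features = fs.features_frame(profiles)
labels = truth["progressed"].astype(float).to_numpy()

results = fs.ProgressionScoreModel(features, labels).fit()
print(results.summary())

calib = results.calibrate_cutpoint(n_bootstrap=1000, seed=7)
ps = results.progression_scores()
calls = [fs.classify(p, calib.selected_cutpoint) for p in ps]
table = fs.performance(calls, [bool(v) for v in labels])
```

This prints:

```
Progression Score model selection
================================================================
n = 128, cases = 15

Model                            AUC      adj. p  Note
----------------------------------------------------------------
FragDiff                       0.964    9.51e-13  Best model
Frag1 + FragDiff               0.972    3.71e-12  Frag1 is not statistically significant.
SM1 + FragDiff                 0.963    8.47e-12  SM1 is not statistically significant.
MMDiff + FragDiff              0.965    8.42e-12  MMDiff is not statistically significant.
Frag1 + MMDiff + FragDiff      0.972    2.26e-11  Frag1 is not statistically significant. MMDiff is not statistically significant.
SM1 + MMDiff + FragDiff        0.965    4.94e-11  SM1 is not statistically significant. MMDiff is not statistically significant.
----------------------------------------------------------------
Selected: FragDiff
LOOCV AUC: 0.953

Coefficient       estimate     std err     P>|z|
Intercept           -3.942       0.658  2.09e-09
FragDiff          0.004498    0.001136  7.52e-05
```

and the calibration selects cut-point 86 with expected PPV 0.9905; at that
threshold 9 of 128 patients are called (PPV 1.000) and 119 are not
(NPV 0.950). Reading the table: each row is one pre-defined model with its
training AUC and Bonferroni-adjusted likelihood-ratio p-value; on this
simulated cohort the `FragDiff`-only model is preferred because the richer
models' extra predictors add no significant information. The LOOCV AUC is
the honest (held-out) estimate of discrimination. The per-patient PS is
100 × the predicted progression probability; scores at or above the
calibrated cut-point call progression.

## Command line

The same stages are exposed as a CLI for shell use:

```sh
fragscore --seed 7 --out-dir out run          # whole pipeline, synthetic cohort
fragscore --out-dir out simulate              # cohort + ground truth only
fragscore --out-dir out quantify --plate plate.csv --standards std.csv
fragscore --out-dir out features --profiles profiles.csv
fragscore --out-dir out fit --features features.csv --manifest manifest.csv
fragscore --out-dir out calibrate --features features.csv --manifest manifest.csv
fragscore --out-dir out score --features features.csv \
    --model fitted_model.json --calibration calibration.json
fragscore --out-dir out report
```

All tables are CSV with headers; configuration and the calibration object
are JSON. Runs are deterministic given `--seed`.

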