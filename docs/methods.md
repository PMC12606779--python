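# Methods

This note documents the statistical procedures, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## 1. Quantification model

qPCR quantification uses the standard log-linear model
`Ct = m·log10(q) + b` fitted by ordinary least squares in
(log10 quantity, Ct) space over at least three distinct standard levels.
Amplification efficiency is `10^(−1/m) − 1`; a perfectly doubling reaction
has slope −3.3219 and efficiency 1. Curves with non-negative slope or
r² below 0.98 (configurable) are rejected. Unknowns are inverted as
`q = 10^((Ct − b)/m)` from the mean of up to three replicates; a replicate
spread above 0.5 Ct flags high scatter, missing replicates flag dropout,
and a fully missing triplicate quantifies as zero with a no-amplification
flag. The 0.5 Ct and 0.98 bounds are conventional qPCR acceptance values,
not protocol-stated, and are configurable.

Reaction quantities convert to plasma concentration through the extraction
volumes: 2 µL of a 60 µL eluate derived from 500 µL plasma, i.e.
`c = q · (60/2) / 0.5 = 60·q` copies/mL at the defaults. Downstream
arithmetic only ever differences like units, so the concentration unit is
metadata. Duplicate extractions of the same draw are averaged at the
concentration level (not the Ct level), so each extraction's own curve
inversion stays independent.

The ">80 bp" concentration is operationalized as the 80 bp ALU amplicon
quantity from multiplex 1 and ">105 bp" as the 105 bp amplicon from
multiplex 2 — every template at least as long as the amplicon amplifies.

## 2. QC gates

All timing windows are inclusive at both endpoints; the transit rule fails
only strictly beyond the bound:

| rule | bound | default |
|---|---|---|
| transit time | receipt − collection ≤ 120 h | fail if > 120 h |
| draw-2 window | 12–21 days after first treatment | inclusive |
| scan window | 9–12 weeks after draw 1 | inclusive |
| IPC shift | \|sample IPC mean Ct − run median\| ≤ 1.0 Ct | configurable |
| SVA concordance | \|q₁−q₂\| / mean(q₁,q₂) ≤ 0.30 | configurable |

The internal positive control (IPC) is a spiked synthetic template at
fixed copy number; within a run every sample should report the same IPC
Ct, so a shift against the run median indicates PCR inhibition. The 1.0 Ct
default corresponds to roughly two-fold signal suppression, a conventional
inhibition flag; no protocol value exists. A sample with no IPC
amplification is total inhibition and fails outright. The 265 bp SVA
amplicon is quantified in both multiplexes from the same extract; the
relative difference uses the symmetric mean denominator so the verdict
does not depend on multiplex ordering, and the 30 % default is likewise a
chosen convention. Clinical exclusions (secondary malignancy, active
autoimmune treatment, recent DVT/PE/sepsis) arrive as manifest booleans —
the assay cannot diagnose them. A patient is excluded iff any hard rule
fails; gating is idempotent and the analyzable/excluded sets partition the
cohort exactly.

Missing timestamps or scans yield *indeterminate* verdicts that are
treated as failures but flagged distinctly, so a lab can distinguish
data-entry gaps from true violations.

## 3. Fragmentomic features

`Frag = max(SM − MM, 0)` per draw; `FragDiff = Frag2 − Frag1`;
`MMDiff = MM2 − MM1`. The floor applies only to the per-draw excesses:
the between-draw differences stay signed, because the background-noise
clean-up role of `MMDiff` (an expected negative coefficient) requires
signed values. Two algebraic invariants are tested: adding a common spike
to both size classes of a draw leaves that draw's excess unchanged
whenever SM ≥ MM (lysis cancellation), and scaling all concentrations by
k > 0 scales all four features by k.

## 4. Logistic model selection

The six pre-defined predictor subsets are fixed a priori; there is no
data-driven feature search. Each is fitted by maximum likelihood using an
iteratively reweighted least squares (Newton) solver with step-halving.
Predictors are standardized internally for conditioning (coefficients are
mapped back to the raw scale); convergence is declared when the largest
score component drops below 1e-8, with a 100-iteration cap.
Quasi-complete separation — diverging coefficients or a perfect fitted
separation — is detected and *flagged*, never raised, so resampling loops
run to completion; flagged fits keep their (divergent) estimates and their
AUC, which remains well-defined. The solver is cross-checked in the test
suite against statsmodels and against direct likelihood minimization; it
is deliberately in-package so the bootstrap can rely on its never-raising
contract.

Significance per coefficient uses Wald z-tests (α = 0.05). The model-level
p-value is a likelihood-ratio test against the intercept-only model, and
the Bonferroni multiplier is fixed at 6, the number of pre-defined models.
AUC is the rank-based (Mann–Whitney) statistic with ties counting one
half, identical to the trapezoidal area under the empirical ROC; it is
verified against exhaustive pair counting and scikit-learn.

Model selection: the default `parsimony-on-flag` rule restricts the
training-AUC argmax to models whose every predictor is significant
whenever at least one such model exists — a larger model whose extra
predictor is not significant is not preferred for a marginal AUC gain.
The literal `highest-auc` rule (argmax with ties broken by fewer
predictors, then canonical order) is available as a configuration option.

LOOCV refits the selected model n times, predicting each held-out patient,
and scores the pooled held-out probabilities with a single AUC. Folds
whose training set collapses to one class predict the training prevalence
and are flagged. The fold structure is per-patient, so the estimate is
invariant to row order. No regularization is applied: at ~128 patients
with at most three predictors, separation is a diagnostic, not a numerical
emergency.

## 5. Progression Score and cut-point calibration

PS = 100 × the selected model's predicted probability, rounded to one
decimal. No further recalibration is applied: observed score values such
as 8.6 or 100.0 are consistent with a probability scale at one-decimal
granularity, and the logistic probability is already the model's best
estimate of progression risk.

The call threshold is calibrated by bootstrap: each of B = 1000 iterations
resamples the n patients with replacement, *refits* the model on the
resample (propagating model uncertainty; a fixed-model rescoring variant
exists behind a flag), scores the resample, and records PPV at every
candidate threshold (integers 0–100) where at least one call is made.
The expected PPV per threshold is the mean over iterations where it was
defined; thresholds producing no calls in an iteration are skipped for
that iteration, not imputed as 1, since imputation would inflate the curve
exactly where data are scarcest. Degenerate all-one-class resamples are
skipped. The selected cut-point is the smallest threshold whose expected
PPV meets the target (99 %) *and* whose every larger defined threshold
also meets it — a dip above the candidate would make calls at the
candidate unsafe. If no threshold qualifies the calibration fails loudly,
reporting the best achievable expected PPV. A call is made at
PS ≥ cut-point (boundary inclusive).

Empirical PPV is not monotone in the threshold on an arbitrary fixed
dataset (removing a true positive while a lower-scored false positive
remains called lowers it); it is monotone when the score ranks cases
strictly above controls, and the expected-PPV curve rises with the
threshold in the mean under a monotone-likelihood-ratio score. The tests
assert these latter two properties.

## 6. Synthetic cohort generator

The generator emulates the structure the analysis assumes, with every
parameter configurable:

- n = 128 patients, progression prevalence 20/128 ≈ 15.6 % (Bernoulli).
- Baseline: `MM1 ~ logNormal(log 2000, 0.8)` copies/mL and short-fragment
  excess `Frag1 ~ logNormal(log 300, 0.8)`; `SM1 = MM1 + Frag1`.
  cfDNA concentrations are positive and right-skewed, hence log-normal
  marginals; the absolute scale is a plausible choice, not a measured one.
- Draw 2: `Frag2 = Frag1·exp(N(0, 0.35))`, plus, for progressors, an
  additive effect `~ logNormal(log 1500, 1.0)` copies/mL. The heavy lower
  tail deliberately produces occasional low-shedding progressors that no
  threshold can call — the realistic ceiling on sensitivity.
  `MM2 = MM1·exp(N(0, 0.25))`.
- Artifacts, independent Bernoulli per draw/patient: WBC lysis (rate 0.05)
  adds a common genomic-DNA spike to SM and MM sized to multiply raw SM by
  2–10×, leaving SM − MM nearly unchanged; PCR inhibition (rate 0.03)
  shifts every target's Ct by +2.5 including the IPC, so the IPC gate
  catches it; non-cancer cfDNA elevation (rate 0.08) multiplies both size
  classes of draw 2 by exp(U(log 1.3, log 3)), the proportional pattern
  the fragmentomic difference largely cancels.
- Plates: Ct from the target's standard curve plus N(0, 0.15) per
  replicate, triplicates, both multiplexes; Ct beyond 40 cycles is
  missing. Default curves: slope −3.3219 (short targets), intercepts
  37–39.
- Timestamps satisfy every gate by default; violation rates exist per gate
  for testing the exclusion machinery.
- The interference panel mirrors a small acute-condition study (stroke 3,
  asthma 2, COPD 3, diabetic ketoacidosis 3, IBD 4, myocardial
  infarction 2, rheumatoid arthritis 5, seizure 3, viral infection 5, plus
  9 healthy controls) with condition-specific proportional multipliers on
  the post-event draw; a short-only elevation mode generates the pattern
  that genuinely mimics progression.

What the generator does **not** emulate: between-site batch effects,
assay drift over calendar time, fragment-length distributions (only the
two amplicon-thresholded concentrations are modelled), correlated
missingness, or imaging error in the outcome labels. Passing tests
therefore demonstrate the *pipeline's* correctness and the claimed
robustness mechanisms under the stated generative assumptions — not
clinical performance on real cohorts, whose effect sizes and noise are
unknown here.

Under these defaults the training AUC of the two-predictor models
typically lands in the mid-0.9s at n = 128 — the same regime as a
well-separated monitoring assay — and the calibrated cut-point lands in
the mid-80s to 100 depending on the seed, with zero training-cohort false
positives at the selected threshold.

## 7. Problem sizes and determinism

Tests and the acceptance script use the study-scale cohort (n = 128,
B = 1000 bootstrap iterations) for the calibration checks; parameter
recovery uses 200 replicates at n = 2000, and large-sample generator
recovery uses a single n = 5000 cohort. All randomness flows from
explicit `numpy.random.default_rng` seeds; identical configuration and
seed reproduce results bit-for-bit, including output files.

## 8. Known limitations

- The IPC-shift and SVA-concordance thresholds and the standard-curve
  acceptance bounds have no protocol-stated values; defaults are
  field conventions and should be re-validated per instrument.
- The bootstrap expected PPV is a mean over resamples; a lower confidence
  bound would be more conservative and is a noted alternative, not the
  default.
- With very small cohorts or perfectly separated data the refit-bootstrap
  produces many separated fits; flags propagate but coefficient values in
  those iterations are extreme (their rank-based scoring remains valid).
- The manifest schema is a minimal reconstruction; multi-site studies will
  carry more structure (site ids, instrument ids) than modelled here.
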