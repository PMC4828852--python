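# Methods

## The modelling problem

Dobutamine stress echocardiography (DSE) provokes ischemic wall-motion
abnormalities in myocardium supplied by a stenotic coronary artery.  The
conventional readout is visual: an expert grades each of 16 left-ventricular
segments 1 (normal) to 4 (dyskinetic) at rest and peak stress; the mean grade
over interpretable segments is the wall motion score index (WMSI), and a new
or worsening dyssynergy makes the test positive.  Speckle-tracking imaging
yields, in parallel, a large table of quantitative per-segment parameters —
longitudinal velocities (S′, E′, A′), times to peak, longitudinal/radial
systolic, post-systolic and maximal strain, strain rates, radial displacement
— at rest and stress, for the 12 segments visible in the apical 4- and
2-chamber views.  The question this package operationalizes: can many weakly
informative quantitative parameters be combined into a classifier for
angiographic stenosis (≥50 %, per patient and per vessel) that beats the
visual read?

## The three-step construction

**Step 1 — univariable screening.**  For each candidate covariate *a* — one
(parameter, segment, phase) triple, analysed separately per segment because
deformation amplitudes are location-dependent, plus the patient-level
ΔWMSI = WMSI_stress − WMSI_rest — a simple logistic regression
P(y=1) = φ(β₀ₐ + β₁ₐx) is fitted by maximum likelihood on complete cases,
with φ(y) = eʸ/(1+eʸ).  Covariates with a two-sided Wald p < 0.05 are
retained.  No multiplicity correction is applied across the several hundred
tests: that is a property of the modelled procedure and directly feeds the
overfitting analysis.  For each retained covariate an optimal classification
threshold Tₐ ∈ (0,1) on the fitted-probability scale is computed by
maximizing Youden's J (sens + spec − 1) over the intervals between observed
fitted probabilities, returning the midpoint of the maximizing interval
(an accuracy-maximizing criterion is available by configuration).  The
equivalent raw-scale cutoff (logit Tₐ − β₀ₐ)/β₁ₐ is stored with each
feature; this is the number such models tabulate next to each variable.

**Step 2 — rescaling with zero imputation.**  Each raw value x is replaced
by the rescaled response

    r(x) = (φ(β₀ₐ+β₁ₐx) − Tₐ)/(1 − Tₐ)   if φ(β₀ₐ+β₁ₐx) > Tₐ
    r(x) = (Tₐ − φ(β₀ₐ+β₁ₐx))/Tₐ          if φ(β₀ₐ+β₁ₐx) ≤ Tₐ

and a missing value by 0.  r ∈ [0,1] is the normalized distance of the
fitted probability from the covariate's own classification threshold: 0 at
the threshold (and for missing data), approaching 1 deep inside either
class, continuous across the branch boundary and monotone in |p − Tₐ|
within each branch.  Two consequences are worth stating plainly.  First,
missingness can never block a prediction — an uninterpretable segment simply
casts no vote.  Second, r is *unsigned*: a value far on the healthy side of
the threshold scores as high as one far on the diseased side, so the
direction of the deviation is not recoverable downstream.  This is
implemented exactly as specified; it measurably limits how much univariable
signal survives into step 3 and contributes to the validation collapse the
pipeline reproduces.  The branch condition compares φ(β₀+β₁x) with Tₐ — the
only reading under which both branch denominators and the [0,1] range are
coherent, since Tₐ lives on the probability scale; a literal comparison of
the linear predictor with Tₐ is available behind the
`strict_linear_branch` flag.  Zero imputation is applied identically at
training and prediction time.

**Step 3 — stepwise combination.**  On the complete rescaled matrix, one
logistic model per endpoint (any stenosis; LAD; LCX; RCA — built fully
independently) is selected by bidirectional stepwise search from the
intercept-only model, using AIC as the criterion, and refitted by maximum
likelihood on the final set.  The AIC criterion was chosen because it is
reproducible and has no arbitrary enter/remove levels; classic
forward-0.05/backward-0.10 p-value stepping is available by configuration.
Main effects only.  If the final refit shows (quasi-)complete separation —
common at n≈150 with dozens of candidate features — the coefficients come
from an L2-penalized refit (C = 10) with a logged warning.  Classification
is positive when the predicted probability is ≥ the decision threshold
(default 0.5; configurable, including a Youden-optimal-on-training mode).
The fitted model acts as a weighted vote over single-covariate classifiers,
each voter reporting how decisively it sits away from its own threshold.

**Study design.**  `run_study` fits everything on the construction ("test")
cohort only and evaluates all four models plus the visual comparator on both
the construction and the held-out validation cohort, reporting sensitivity,
specificity, PPV and NPV as percentages with 95 % CIs per group × method.

## Evaluation machinery

Confidence intervals are Wilson score by default (never leaves [0,100],
good small-sample behavior); Clopper-Pearson is available by configuration.
The underlying study printed CIs without stating the method, so the exact
interval bounds are not a reproduction target.  Two estimates are called
significantly different at the 0.05 level only when their 95 % CIs do not
overlap (a shared endpoint counts as overlap) — conservative, but it is the
procedure being modelled.  An empty denominator (e.g. PPV with no positive
calls) yields an explicitly undefined metric, never a silent 0.  Observer
reproducibility is summarized as the mean percentage difference
|v₁−v₂|/((v₁+v₂)/2) over paired measurements, absolute-valued (all reported
values of such tables are nonnegative), with zero-mean pairs excluded under
a warning.  Printed-style percentages round half-away-from-zero to one
decimal.

## The synthetic cohort generator

No patient data accompany the study, so a seeded generator supplies cohorts
with the statistical structure the analysis assumes.  Defaults are the study
conditions: construction cohort n = 151 with any-stenosis prevalence 0.503
and missingness 2.1 % (rest) / 5.0 % (stress); validation cohort n = 105,
prevalence 0.657, missingness 2.5 % / 5.2 %.

* **Disease.**  Any-stenosis is Bernoulli(prevalence).  Diseased patients
  draw independent per-vessel flags (defaults LAD 0.55, LCX 0.50, RCA 0.55)
  conditioned on at least one positive, giving a realistic single/double/
  triple-vessel mix (≈1.8 diseased vessels per diseased patient).
* **Parameters.**  Each of the 13 parameters has a healthy rest mean ± SD
  and a stress response taken from published normal ranges (e.g. S′ 6.0 ±
  1.2 cm/s rising by 3 under dobutamine; longitudinal systolic strain
  −18 ± 3.5 % deepening by 2; time to peak S′ shortening from 150 to 90 ms).
  Values are Gaussian with a shared patient-segment noise component
  (fraction 0.3) inducing rest-stress correlation.  Post-systolic strain is
  generated as systolic strain minus a half-normal extra shortening, and
  maximal strain is derived from the two by the larger-magnitude rule, so
  the derived-measure identities hold in the synthetic data.
* **Ischemia.**  Applied at stress only, in stenotic territories only
  (conventional ASE assignment: anterior wall + apex + mid/apical septum →
  LAD, basal/mid lateral → LCX, inferior wall + basal septum → RCA;
  overridable), as an additive shift of `effect_size` SDs in the
  physiological direction: strain and velocities blunted toward zero, times
  to peak prolonged, post-systolic and positive systolic strain increased.
  The default effect size 0.8 SD is a moderate single-segment effect —
  deliberately in the range where univariable screening has partial power,
  which is the regime the construction operates in.
* **Visual assessment.**  WMSI_rest ≈ 1 + |N(0, 0.03)|; the stress increment
  is |N(0.275·effect, 0.08 + 0.125·effect)| in diseased patients and
  |N(0, 0.08)| in healthy ones, clipped to [1,4] — at the default effect
  size this reproduces group means near 1.02/1.21.  Both the mean and the
  extra dispersion scale with effect size so that a zero effect gives a
  fully null cohort.  The binary visual call is ΔWMSI ≥ 0.125, giving
  sensitivity ≈ 0.75 and specificity ≈ 0.88 at the default effect — the
  operating point of an expert reader.  WMSI is simulated directly at the
  patient level (the models consume only ΔWMSI), not from 16 per-segment
  grades.
* **Missingness.**  Missing completely at random per (segment, parameter,
  phase) cell at the phase-specific rate; only marginal uninterpretable
  rates are reported for the real data, so no informative mechanism is
  modelled.

What the generator does **not** emulate: image-level noise and speckle
decorrelation at high heart rate, load dependence of deformation, tethering
between adjacent ischemic and non-ischemic segments, non-MCAR missingness
(dropout concentrates in specific walls in practice), inter-parameter
correlation beyond the shared segment noise, and any relation between
stenosis severity and effect magnitude.  Tests passing on these cohorts
therefore validate the *procedure* — its type-I error, selection behavior,
optimism and determinism — not the clinical accuracy of any fitted model.

## Numerical choices

* Logistic fits: `statsmodels` Logit (Newton), maxiter 100.  A univariable
  fit is flagged degenerate (excluded, with reason logged) on
  non-convergence, |β| > 50, a constant covariate, all-missing data, or
  fewer than two complete cases in either class.
* The stepwise AIC sweep compares thousands of small candidate fits; these
  use an internal damped-Newton likelihood evaluation with step halving,
  returning AIC = 2k − 2ℓ, and treat diverging candidates (|β| > 100) as
  unavailable — the same outcome a failed ML fit would have.  Final
  coefficients always come from a `statsmodels` (or, under separation,
  scikit-learn penalized) refit.
* Threshold search: J is piecewise constant between consecutive distinct
  fitted probabilities; the search enumerates all intervals via suffix-sum
  histograms, merges tied adjacent intervals, and returns the midpoint of
  the first maximizing run.  Classification at a threshold t is `p > t`
  inside the search; the model-level decision threshold uses `≥` (both
  conventions documented, boundary cases tested).
* Determinism: one integer seed per run; the two cohort seeds are spawned
  from it through `numpy` SeedSequence (kept below 2³¹).  Model JSON and
  report CSV serialization is key-sorted with fixed float formatting, so
  identical configurations produce byte-identical artifacts.
* Ties in the maximal-strain rule return the systolic value; ΔWMSI may be
  negative (biphasic response) and is not clipped.

## Problem sizes in the shipped analyses

The replicate experiments ship at sizes chosen to make their statistical
claims at desk scale: the screening type-I check uses four null cohorts of
n = 300 (≈1 250 independent univariable tests, binomial 3-SD band around
0.05); selection consistency uses 200 seeded replicates of n = 400 with one
informative and nine null features; the overfitting experiment uses 50 seeds
per training size (50 / 151 / 500 patients) for the acceptance suite and a
10-seed default in the analysis driver.

## Known limitations

* The unsigned rescaling discards deviation direction by construction (see
  above); a signed variant would likely validate better but is out of scope.
* Per-vessel models are evaluated against every patient's vessel label; the
  modelled study does not state its per-vessel denominators.
* CI-overlap is a conservative significance rule; no paired comparisons
  (McNemar, DeLong) are attempted because the modelled procedure uses none.
* The generator's territory map is one convention among several in use;
  it is overridable but the default is fixed for reproducibility.
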