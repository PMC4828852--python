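# dse-ischemia

Multiparametric logistic modelling of stress-induced myocardial ischemia
from quantitative dobutamine-stress-echocardiography (DSE) parameters.

Quantitative speckle-tracking echocardiography produces, for every patient,
hundreds of per-segment measurements — longitudinal velocities (S′, E′, A′),
times to peak, longitudinal/radial systolic, post-systolic and maximal
strain, strain rates, radial displacement — at rest and at peak dobutamine
stress.  This package implements, as a tested reusable pipeline, the
construction of diagnostic models that combine those parameters into
per-patient and per-vessel classifiers of angiographic coronary stenosis
(≥50 %), and the evaluation framework that asks whether such models beat
expert visual wall-motion reading.  It is aimed at biostatisticians and
echo researchers studying multiparametric stress-echo classifiers and, more
broadly, the optimism of apparent model performance in small clinical
cohorts.

## The construction

For each endpoint y (any stenosis; LAD; LCX; RCA) and each covariate *a* —
one (parameter, segment, phase) triple, plus the visual covariate
ΔWMSI = WMSI_stress − WMSI_rest:

1. **Screening.**  Fit P(y=1) = φ(β₀ₐ + β₁ₐx), φ(y) = eʸ/(1+eʸ), on
   complete cases; keep covariates with Wald p < 0.05; for each, find the
   Youden-optimal probability threshold Tₐ and the raw-scale cutoff
   (logit Tₐ − β₀ₐ)/β₁ₐ.
2. **Rescaling.**  Replace each raw x by
   r(x) = (φ(β₀ₐ+β₁ₐx) − Tₐ)/(1 − Tₐ) if φ(β₀ₐ+β₁ₐx) > Tₐ, else
   (Tₐ − φ(β₀ₐ+β₁ₐx))/Tₐ, and missing values by 0 — a complete matrix of
   [0,1] distance-from-threshold scores in which a missing measurement
   simply casts no vote.
3. **Stepwise combination.**  Bidirectional AIC stepwise logistic
   regression over the rescaled features, one model per endpoint, fitted on
   the construction ("test") cohort only and evaluated on both it and a
   held-out validation cohort with sensitivity/specificity/PPV/NPV and 95 %
   Wilson CIs; two estimates differ significantly only when their CIs do
   not overlap.

Because no patient data are available, a seeded synthetic cohort generator
(`dse_ischemia.synthetic`) supplies cohorts with the study's structure:
151-patient construction cohort at any-stenosis prevalence 0.503 and
105-patient validation cohort at 0.657, territory-linked ischemic shifts of
the stress-phase parameters, visual WMSI scoring, and missing-completely-
at-random segment dropout (2.1–2.5 % rest, 5.0–5.2 % stress).  See
`docs/methods.md` for the full model and its assumptions.

## Worked example

```python
from dse_ischemia import StudyConfig, run_study, simulate_cohort

config = StudyConfig(seed=0)
train = simulate_cohort(config.train, group="test")
valid = simulate_cohort(config.validation, group="validation")
report = run_study(train, valid, config)
print(report.to_text())
```

prints (abridged):

```
Method                                        Group       Sens % (95% CI)       Spec % (95% CI)
Visual wall motion analysis                   test        71.8 (60.5; 81.0)     88.8 (80.0; 94.0)
Visual wall motion analysis                   validation  70.5 (59.6; 79.5)     85.2 (67.5; 94.1)
Model for at least one stenosis per patient   test        88.7 (79.3; 94.2)     91.2 (83.0; 95.7)
Model for at least one stenosis per patient   validation  60.3 (49.2; 70.4)     59.3 (40.7; 75.5)
```

Read: on its own construction cohort the combined model looks clearly
better than the visual read (sensitivity 88.7 % vs 71.8 % at comparable
specificity), but on the held-out cohort its sensitivity and specificity
collapse to 60.3 %/59.3 %, below visual assessment — apparent performance
was optimism, not accuracy.  The same study can be run from the shell:

```bash
dse-ischemia report --seed 0 --out-dir results/study
```

The numbered scripts under `analysis/` walk the same pipeline step by step
(simulate → screen → fit → evaluate → overfitting experiment), each writing
its tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py --seed 0
python analysis/02_screen_features.py
python analysis/03_fit_models.py
python analysis/04_evaluate_performance.py
python analysis/05_overfitting_experiment.py
```

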