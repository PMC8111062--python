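# spectrodx

Simulation and diagnostic-accuracy analysis for a serum ATR-FTIR
(attenuated total reflectance Fourier-transform infrared) liquid-biopsy
test for brain tumours.

## The problem

Patients presenting in primary care with non-specific neurological
symptoms rarely have a brain tumour (population prevalence ~1–3% among
those referred for imaging), so a cheap blood test that triages who should
be scanned first has large clinical value. One candidate technology dries
3 µl of serum into each of three wells on a disposable infrared slide and
records three spectra per well — nine absorbance spectra per patient over
the fingerprint region (1800–900 cm⁻¹). A per-spectrum machine-learning
classifier emits a cancer probability for each spectrum, and the patient
is called **cancer** when at least 5 of the 9 spectra vote cancer.

`spectrodx` is a tested re-implementation of the full analysis chain for
this kind of study, aimed at biostatisticians and method developers who
want to stress-test the statistics without access to the original spectra:

* **`spectrodx.simulate`** — a generative model of serum cohorts: Gaussian
  band mixtures with a small class effect, well-level baseline/offset/scale
  nuisance, scan-level noise, configurable prevalence and tumour-subtype
  mix, all under one seed.
* **`spectrodx.preprocess`** — region selection, polynomial or rubberband
  (convex-hull) baseline correction, Savitzky–Golay smoothing, vector/minmax
  normalisation, composed in a fixed order.
* **`spectrodx.classify`** — regularised-logistic or random-forest
  per-spectrum classifiers with patient-grouped, class-stratified
  cross-validation and consensus-level threshold tuning.
* **`spectrodx.consensus`** — the 5-of-9 vote, and patient-level ROC curves
  by threshold sweeping.
* **`spectrodx.metrics`** — diagnostic accuracy statistics in the
  statsmodels idiom: build `DiagnosticAccuracy` from counts or
  predictions, `fit()`, and read a `DiagnosticAccuracyResults`.

## The statistics

For a patient-level confusion matrix (TP, FP, FN, TN) the package computes

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)                NPV = TN/(TN+FN)
    accuracy = (TP+TN)/N            prevalence = (TP+FN)/N

each with a binomial confidence interval, by default the Wald interval
p ± z·√(p(1−p)/n) clipped to [0, 1] (Wilson available). Precision is the
CI half-width in percentage points, `100·z·√(p(1−p)/n)`, and
`required_n` inverts it into a cohort-size calculation at a given
prevalence. Predictive values are transported to other population
prevalences π either exactly via Bayes' theorem,

    PPV(π) = sens·π / (sens·π + (1−spec)(1−π)),

or by the linear rescaling `PPV·π/prevalence` sometimes quoted in
screening discussions (the two differ; reports label the method). The
5-of-9 consensus vote boosts patient-level accuracy above per-spectrum
accuracy p according to the binomial tail Σ_{j≥5} C(9,j)·p^j·(1−p)^{9−j}.

## Worked example

The study-style report from patient-level confusion counts (54 true
positives, 65 false positives, 13 false negatives, 253 true negatives):

```python
import spectrodx as sx

res = sx.DiagnosticAccuracy.from_counts(tp=54, fp=65, fn=13, tn=253).fit()
print(res.summary())
```

```
Diagnostic accuracy report
==========================

Confusion matrix (test rows x reference columns):
               Positive  Negative  Total
Test positive        54        65    119
Test negative        13       253    266
Total                67       318    385

Metric        Estimate 95% CI lower 95% CI upper
sensitivity        81%          71%          90%
specificity        80%          75%          84%
prevalence         17%          14%          21%
ppv                45%          36%          54%
npv                95%          93%          98%
accuracy           80%          76%          84%

CI method: wald; sensitivity precision (CI half-width): +/-9.5 percentage points
```

The test detects 81% of tumours and clears 80% of tumour-free patients; in
this enriched cohort (17% prevalence) a positive result is right 45% of
the time while a negative result is right 95% of the time. Transporting to
a primary-care population at 3% prevalence:

```python
ppv, npv = res.adjust_predictive_values(sx.PrevalenceScenario(0.03, "bayes"))
lin, _   = res.adjust_predictive_values(sx.PrevalenceScenario(0.03, "linear"))
# PPV at 3% prevalence: 10.9% (Bayes), 7.8% (linear rescaling)
```

An end-to-end synthetic run — simulate a 385-patient cohort (67 cancers),
preprocess, cross-validate a classifier, vote, and report — is one command:

```
spectrodx simulate -o run/ --seed 1
spectrodx evaluate -i run/cohort -o run/eval --seed 1
```

or, from Python, `sx.SpectralDiagnosticModel(records, spectra).fit()`.
Under the default simulator settings this lands near 82% sensitivity, 81%
specificity and patient-level AUC ≈ 0.88.

The same report is available from the command line for any counts:

```
spectrodx report-from-counts 54 65 13 253 -p 0.03
```

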