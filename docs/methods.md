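# Methods

## Generative model for synthetic serum spectra

Real serum ATR-FTIR cohorts for this application are not publicly
deposited, so every downstream stage is exercised on cohorts from the
package's own generative model. A spectrum on the fingerprint grid
(default 1800–900 cm⁻¹, 451 points ≈ 2 cm⁻¹ spacing) is

    A(ν) = s_w · Σ_b a_b(c) · exp(−(ν − μ_b)² / 2σ_b²) + B_w(ν) + o_w + ε(ν)

with Gaussian bands at 1650, 1540, 1450, 1400, 1240 and 1080 cm⁻¹
(amide I/II, CH bending, COO⁻, amide III/phosphate, carbohydrate–nucleic
acid backbone; amplitudes in arbitrary absorbance units). The class effect
is a fractional amplitude shift on the 1540, 1240 and 1080 cm⁻¹ bands:
`a_b(cancer) = a_b·(1 + effect_size)`, default `effect_size = 0.03`, small
enough that the two class means are visually indistinguishable.

Replicate structure mirrors the assay: 3 wells × 3 scans = 9 spectra per
patient. Nuisance draws are layered at the level where the physical
process lives:

| term | level | default | emulates |
|---|---|---|---|
| `s_w` multiplicative scale | well | SD 0.05 | droplet thickness |
| `B_w(ν)` polynomial (degree 2) | well | coeff. SD 0.02 AU | scatter/drift |
| `o_w` additive offset | well | SD 0.03 AU | slide positioning |
| `ε(ν)` white noise | scan, point | SD 0.08 AU | detector noise + proxy for biological variability |

Scans within a well share the well draws, so within-well correlation
exceeds between-well correlation (a tested property). The additive-noise
default is deliberately large relative to instrument noise: the model has
no explicit between-patient biological variation term, and the noise level
was fixed, once, so that a default 385-patient cohort is hard but
learnable — cross-validated patient-level performance lands near the
80%-sensitivity/80%-specificity regime that a realistic serum test
occupies, rather than at 100%.

**What the simulator does not emulate:** instrument physics (ATR
penetration depth, background-well subtraction), water-vapour/CO₂
interference, drying-pattern chemistry, genuine biochemical differences
between tumour subtypes (subtype labels are carried in the truth table but
do not alter spectra), and structured patient-level covariance. Passing
tests therefore demonstrate that the *pipeline and statistics* behave
correctly under the assumed replicate and noise structure — not that any
classifier would achieve these numbers on real serum.

Cohort assembly: the cancer count is `round(n_patients × prevalence)`
(half away from zero, so 385 × 67/385 is exactly 67); subtypes are
apportioned among cancers by largest remainder from the configured mix
(default glioblastoma-dominant: 34/67 glioblastoma, 16/67 metastasis,
5/67 meningioma, 12/67 other) and shuffled. One `numpy` generator seeded
by `SimConfig.seed` drives everything; identical configs give
byte-identical cohorts.

## Preprocessing

Fixed stage order **region → baseline → smooth → normalise**. Normalising
last makes features scale-free, cancelling the multiplicative well effect.
Defaults — fingerprint region, rubberband baseline, no smoothing, unit
vector normalisation — are conventional serum-FTIR chemometrics; nothing
here claims to match the original (undisclosed) preprocessing, and every
stage is configurable. The rubberband baseline is the lower convex hull of
the trace (monotone-chain construction) interpolated and subtracted;
polynomial baselines are ordinary least squares. Smoothing is
Savitzky–Golay, which reproduces polynomials up to the filter order
exactly — the property the tests pin.

## Classification and threshold tuning

Two estimator families stand behind one contract: L2 logistic regression
on standardised features, and a random forest (default family). The
original classifier is proprietary; the package's claims are about the
surrounding statistics, not about reproducing its weights.

Cross-validation is grouped at **patient** level and class-stratified
(±1 patient per fold): replicate spectra are strongly correlated, so
spectrum-level splits would leak and inflate performance. Every reported
number derives from out-of-fold probabilities.

The vote threshold is tuned **post-consensus**: for each candidate
threshold t (0 plus every distinct out-of-fold probability; votes use the
inclusive p ≥ t), patient-level consensus predictions are formed and the
balanced objective max min(sensitivity, specificity) is evaluated — ties
prefer smaller |sens − spec|, then the lower threshold. An alternative
objective maximises sensitivity subject to a specificity floor. Whether
the original study tuned pre- or post-consensus is not documented;
post-consensus matches the per-patient reporting convention and is the
package's choice.

A useful identity makes threshold sweeps cheap: a patient with k spectra
is called cancer at threshold t iff its m-th largest probability is ≥ t
(m = 5 for complete 9-spectrum patients), so each patient collapses to a
single order-statistic score and ROC/tuning are O(n log n). The per-vote
aggregator is retained and tested for exact equivalence.

## Consensus and ROC

Default rule: cancer iff ≥ 5 of the expected 9 votes. For incomplete
patients (the study protocol is silent) the default is strict majority of
available votes with exact ties resolved **to cancer**: the test's
clinical role is rule-out, so ambiguity must not produce false
reassurance. A hard-error policy is configurable. ROC curves sweep the
sorted unique probabilities plus 0 and just-above-max; sensitivity is
non-increasing and specificity non-decreasing in the threshold by
construction, and AUC is the trapezoid over (1−specificity, sensitivity),
which equals tie-adjusted pairwise concordance of the patient scores.

## Diagnostic metrics

Wald is the default CI because it reproduces the published six-metric
panel (point estimates and all interval bounds) exactly after
whole-percent rounding, which pins the CI method the original analysis
must have used; Wilson is available as an option. z for 95% is the exact
normal quantile (≈1.959964). Zero-denominator metrics are flagged
undefined (NaN + error on `conf_int`), never silently 0. Display rounding
is nearest whole percent for report tables and one decimal for precision
values.

Prevalence transport implements both the exact Bayes identities and the
linear rescaling `PPV·π/prevalence`. At the study's operating point and
π = 0.03 these give 10.9% and 7.8% respectively — they genuinely differ,
and neither is forced onto the other; reports always label the method.
`required_n` inverts the half-width formula with expected positives
N × prevalence treated continuously, then adjusts to the smallest integer
N meeting the target.

## Problem sizes and seeds in the checks

The statistical checks use: 5 seeds × 300-patient null cohorts for the
no-signal AUC calibration (band [0.40, 0.60]); 100 replicates of
385-patient cohorts with per-spectrum vote noise calibrated through the
binomial tail so true patient-level sensitivity is exactly 0.8, for Wald
coverage; 10,000 simulated patients per accuracy point for the
consensus-vote closed form; 1,000 patients for the permutation-null ROC
band. The end-to-end acceptance run uses the logistic family on a full
385-patient default cohort. All seeds are fixed in the tests or derived
from the acceptance script's `--seed`.

## Known limitations

* The simulator's difficulty is set by scan noise, not by biological
  heterogeneity; effect-size/noise trade-offs on real serum will differ.
* Wald intervals undercover slightly for small n and extreme p (the
  coverage check shows ~92–96% at n = 67, p = 0.8); Wilson is provided
  for users who need guaranteed-better small-sample behaviour.
* The linear prevalence rescaling is not a probability statement and can
  exceed the Bayes value by construction at low prevalence.
* Patient-level AUC from figure-only sources is not a target anywhere in
  the package.
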