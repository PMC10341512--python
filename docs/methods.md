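# Methods

This note documents the models, defaults and numerical choices behind
`metamark`, and what the synthetic-data generator does and does not
emulate.

## Data model and normalization

A `FeatureTable` is a sample × metabolite matrix of non-negative peak
areas with one group label per sample and optional retention-time / m/z
annotations. Missing cells are NaN throughout — never zero-filled — and
zero intensities are treated as LC–MS non-detects. The normalization chain
is fixed in order:

1. **Half-minimum imputation**: each missing/zero cell becomes half the
   minimum positive observed value of that metabolite, a conventional
   proxy for values below the detection limit. Metabolites with no
   positive observation are dropped with a warning. Imputation runs
   *before* total sum scaling so that every sample's TSS denominator
   covers the same metabolite mass.
2. **Total sum scaling (TSS)**: each row divided by its total, making rows
   sum to one. This removes any per-sample multiplicative factor (tissue
   amount, injection volume) exactly.
3. **log₁₀ transform**.

Fold changes are computed on the TSS scale because the screening threshold
(1.5) is ratio-scaled; t-tests run on the log scale where intensities are
closer to normal with stabilized variance. Re-normalizing an
already-normalized table raises instead of silently rescaling; this guard
caught real ordering mistakes during development.

Feature tables are parsed from comma- or tab-delimited text (chosen by
extension), samples as rows; empty cells, `NA` and `NaN` are missing. No
abundance-based feature filtering is applied by default — the pipeline
assumes an already-curated list of identified metabolites.

## Univariate screen

Per pairwise comparison (g₁, g₂): FC = mean(g₁)/mean(g₂), two-sided
two-sample t-test (pooled variance by default, Welch by flag), and
Benjamini–Hochberg step-up adjustment with the family defined as all
metabolites tested in that one comparison; comparisons are adjusted
independently. A metabolite is significant when `p_adj < alpha` (0.05) and
the fold change lies outside (1/1.5, 1.5). The FC rule is symmetric
although often quoted one-sidedly as “> 1.5”, because depletion is
screened the same as accumulation. Zero-variance metabolites with equal
group means get p = 1 by convention and are logged. BH is delegated to
statsmodels; the test suite verifies it against a direct evaluation of the
step-up definition.

## PLS-DA

Two-class PLS1 via NIPALS, written here: columns of X are autoscaled
(mean 0, sd 1, ddof 1), the class vector coded ±1 and centered. Each
component takes w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, c = yᵀt/tᵀt,
then deflates X and y. Successive scores are mutually orthogonal
(asserted to 1e-8); extraction stops early if the residual weight
collapses below 1e-12, recording the actual component count. Predictions
use B = W(PᵀW)⁻¹c. The implementation is cross-checked in tests against
scikit-learn's independent PLS solver to 1e-6 (observed agreement
~1e-14).

Diagnostics: R²(k) is the cumulative fraction of class-variable variance
explained in-fit (non-decreasing in k). Q²(k) = 1 − PRESS/SS over
held-out predictions, with SS the held-out deviation from the
training-fold class mean. Accuracy is the fraction of held-out samples
with correctly signed predictions; a resubstitution variant exists behind
a flag. Cross-validation is leave-one-out when n < 20 — the regime of
6–8 samples per group, where 10-fold would be degenerate — and stratified
10-fold (re-seeded if a fold loses a class) otherwise. Scaling parameters
are re-estimated inside every training fold; a test compares against a
deliberately leaky variant and requires them to differ. Five components
are fitted by default.

With tens of autoscaled noise features and a dozen samples, the NIPALS
weight vector retains appreciable noise mass (sample correlations scale
as 1/√n), so cross-validated Q² can sit far below an excellent R² even
for well-separated groups. That optimism gap is expected behavior in this
small-n regime, not a defect, and is why Q² — not R² — is the reported
predictive diagnostic.

## ROC marker screen

Per metabolite, the raw AUC is the Mann–Whitney probability that a random
case exceeds a random control (ties ½), computed by the rank identity and
verified in tests against exhaustive pair counting. The oriented AUC is
max(A, 1−A) with the direction recorded (“case-high” / “control-high”);
orientation is required because good markers may be depleted (FC < 1) in
the case group. The screen is independent of the univariate filter — a
metabolite can be a retained marker without passing the FC rule. Retention
uses a strict threshold, AUC > 0.9.

Optimal cutoff: the ROC point minimizing √((1−sens)² + (1−spec)²) — the
closest-to-top-left rule, matching common biomarker tooling — with ties
broken toward higher specificity and the all-negative endpoint excluded.
The 95% CI is a stratified percentile bootstrap (resampling within class,
500 replicates by default, upper bound clipped at 1).

## SVM panel selection

The classifier is a soft-margin linear SVM (hinge loss + L2 penalty,
C = 1 by default, scikit-learn's libsvm backing). Features are z-scored
with training-partition parameters only; margin classifiers are
scale-sensitive and metabolite intensities span decades.

Selection is a greedy forward wrapper: starting empty, each step adds the
feature maximizing mean inner-CV accuracy (ties toward the lower column
index, making runs reproducible), stopping at floor(0.5 × d) features.
The panel used on the outer test fold is the earliest prefix of the path
attaining the maximal inner accuracy — reconciling the 50% cap with
reported panels much smaller than half the features. The wrapper sits
inside a repeated (10×) stratified 3×3 nested cross-validation;
per-repeat fold seeds derive deterministically from the master seed.
Metrics (accuracy, sensitivity = TPR of the first-named group,
specificity, balanced accuracy) are percentages over outer-test
predictions pooled across repeats; balanced accuracy is exactly
(sens + spec)/2 on those pooled counts.

Fold-level panels are merged by **selection frequency** across all outer
folds and repeats, ties broken by mean inner accuracy at first inclusion,
then univariate p, then name; the reported panel size is the modal size of
the fold-level best prefixes. How fold-wise selections become one panel is
genuinely open in this design; frequency aggregation is this package's
documented choice, and recovery of planted informative features is
asserted on frequencies pooled over many independent runs (a single
run's best prefixes are often one near-perfect feature, too few to fill a
top-10).

## Phenotype correlation

Pearson r of each metabolite's log₁₀ TSS intensity against immobility
seconds over the samples of a comparison (configurable), p from the
t-distributed transform of r. Flagged when |r| > 0.4 and p < 0.05; no
multiplicity adjustment — the rule is a plain threshold screen, and is
documented as such. Constant metabolites report r = 0, p = 1 with a
degeneracy flag.

## Synthetic data generator

The generator emulates the statistical structure of the four-group
chronic-isolation / fluoxetine design:

* per-metabolite baseline log-mean uniform on [10, 16] (natural log of
  peak area), within-group log-sd 0.25;
* ground-truth effects as multiplicative group fold changes; the default
  spec spikes the published effect magnitudes (0.27–5.08) onto named
  metabolites;
* a per-sample total-intensity drift factor (log-sd 0.15) that TSS removes
  exactly — included so normalization is genuinely exercised;
* non-detects blanked uniformly at rate 0.02;
* group sizes default to 7 (the 6–8 range of the study design);
  n < 3 per group is rejected as downstream CV becomes infeasible;
* immobility = base (150 s) + group shift (default +60 s under chronic
  isolation, +15 s under treatment) + 30 s × residual, where the residual
  couples chosen metabolites' standardized log intensities as
  Σ r_m z_m + √(1 − Σ r_m²)·ε. With one coupled metabolite this is the
  classic construction y ∝ r·z + √(1−r²)·ε whose population correlation
  is exactly r. z is standardized on the TSS scale: the drift factor is
  an artifact removed before any correlation is measured, so coupling to
  the drifted signal would silently attenuate the realized correlation
  below its target (≈0.49 instead of 0.59 under the defaults).

Responder designation from week-0/3/6 immobility follows the >20% rules:
stressed animals are designated when both week-3 and week-6 immobility
exceed baseline by more than 20%; treated animals are responders when
week-6 immobility lies more than 20% below the stressed-group reference
(mean of designated animals at week 6 by default; week 3 via flag, since
either anchor is defensible). All other animals are flagged resilient.

What the generator does **not** emulate: retention-time drift, adducts,
isotopes, correlated metabolite blocks, heavy-tailed or
intensity-dependent noise, and batch effects. Passing recovery tests
therefore demonstrates that the statistics behave correctly under the
stated log-normal model, not that they are robust to every artifact of
real LC–HRMS data.

## Calibration and recovery suites (problem sizes)

The acceptance-style checks run at sizes chosen to keep the full suite in
a few minutes on one CPU while leaving the conclusions stable:

* null false-positive behavior: 200 effect-free tables (117 metabolites,
  7/group); the fraction of runs with any significant metabolite stays
  ≤ 0.05 (the joint FC rule trims borderline BH rejections below the
  nominal level);
* permuted-label nested CV: 40 runs at 10 metabolites, 2 repeats — mean
  balanced accuracy within [40%, 60%];
* PLS-DA null Q²: 50 tables, mean ≤ 0.2;
* spike recovery: 8 metabolites spiked at |fold| ≥ 2, 100 seeds,
  univariate sensitivity ≥ 0.9;
* panel recovery: 5 informative of 20 features, 20 seeds, ≥ 4 recovered
  in the top-10 pooled selection frequencies;
* phenotype coupling at r = 0.59, n = 24: flagged in ≥ 80% of 100 seeds.

## Known limitations

* The pipeline starts at an identified peak table; no raw-spectra
  processing, compound identification or QC-drift correction.
* PLS-DA is two-class only; no VIP scores or permutation testing of the
  model itself.
* The SVM panel uses a linear kernel only, with fixed C by default; panel
  aggregation across folds is a convention, not an estimator with known
  sampling properties.
* Bootstrap CIs are percentile-based; with complete separation at n ≈ 7
  per group they collapse to [1, 1], which overstates certainty at these
  sample sizes.
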