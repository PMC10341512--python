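# metamark

Biomarker discovery for untargeted metabolomics feature tables.

`metamark` implements the complete statistical workflow used to mine
LC–HRMS peak-area tables for candidate markers of a phenotype and of
treatment response: normalization, univariate differential-abundance
screening, PLS discriminant analysis, single-metabolite ROC marker
assessment, multivariate panel selection with a linear SVM under repeated
nested cross-validation, and metabolite–behavior correlation. The package
is aimed at the common preclinical design it emulates by default: four
groups of 6–8 animals (Control, Control+Flx, CSIS, CSIS+Flx — a rodent
chronic-social-isolation model of depression with and without fluoxetine),
~117 identified metabolites per sample, and a forced-swim-test immobility
phenotype. Because raw peak tables from such studies are rarely at hand, a
synthetic-data generator with known ground truth is a first-class part of
the package; every downstream stage is validated against it.

## The statistics at the core

Given a sample × metabolite intensity matrix `X` (rows `i`, columns `j`)
with group labels, the pipeline computes, per pairwise group comparison
(g₁, g₂):

* **Normalization** — half-minimum imputation of non-detects, total sum
  scaling `x̃ᵢⱼ = xᵢⱼ / Σⱼ xᵢⱼ`, then `log₁₀`.
* **Univariate screen** — fold change `FCⱼ = mean₁(x̃ⱼ)/mean₂(x̃ⱼ)` on the
  TSS scale, a two-sample t-test on the log scale, Benjamini–Hochberg
  adjustment across metabolites; significant iff `p_adj < 0.05` and
  `FC ≥ 1.5` or `FC ≤ 1/1.5`.
* **PLS-DA** — NIPALS components on autoscaled X against a centered ±1
  class vector; in-fit R², cross-validated Q² = 1 − PRESS/SS and
  classification accuracy (leave-one-out below n = 20).
* **ROC marker screen** — per metabolite the Mann–Whitney AUC
  (P(random case > random control), ties ½), oriented as max(A, 1−A) so
  depleted metabolites score as markers too; optimal cutoff closest to the
  (0, 1) corner; stratified percentile-bootstrap 95% CI; retained when
  AUC > 0.9.
* **SVM panel** — greedy forward selection maximizing inner-CV accuracy of
  a linear soft-margin SVM, capped at 50% of features, inside a
  10×-repeated 3×3 stratified nested cross-validation; pooled outer-test
  accuracy/sensitivity/specificity/balanced accuracy, and a reported panel
  aggregated by selection frequency.
* **Correlation screen** — Pearson r of each metabolite against immobility
  seconds; flagged when |r| > 0.4 and p < 0.05.

## Worked example

```python
import metamark as mm

spec = mm.default_spec(seed=1)               # study-like ground truth
table, truth = mm.simulate_feature_table(spec)
phenotype = mm.simulate_phenotype(table, spec)
tss, tlog = mm.normalize_chain(table)

uni = mm.univariate_screen(tss, tlog, ("CSIS+Flx", "CSIS"))
print(uni[uni.significant].round(4))
```

```
                           fold_change   p_raw  p_adjusted  significant
metabolite
Sedoheptulose-7-phosphate       2.2314  0.0005      0.0110         True
Myo-inositol                    0.6014  0.0022      0.0438         True
Hexanoylcarnitine               0.4362  0.0001      0.0029         True
Xanthosine                      0.5173  0.0001      0.0029         True
Hypotaurine                     1.7091  0.0001      0.0029         True
Acetyl-L-carnitine              3.0176  0.0000      0.0001         True
```

The six flagged metabolites are exactly the ones the generator spiked for
the treatment-efficacy comparison, with estimated fold changes close to
the injected ones (e.g. Acetyl-L-carnitine: injected 3.31, estimated
3.02). The ROC screen ranks the same signals as near-perfect single
markers, recording which direction discriminates:

```python
sub = tlog.subset_groups("CSIS+Flx", "CSIS")
for r in mm.marker_screen(sub, ("CSIS+Flx", "CSIS"), seed=1)[:4]:
    print(f"{r.metabolite:28s} AUC {r.auc_oriented:.3f} ({r.direction}) "
          f"CI [{r.ci95[0]:.3f}, {r.ci95[1]:.3f}]")
```

```
Acetyl-L-carnitine           AUC 1.000 (case-high) CI [1.000, 1.000]
Hexanoylcarnitine            AUC 1.000 (control-high) CI [1.000, 1.000]
Hypotaurine                  AUC 1.000 (case-high) CI [1.000, 1.000]
Myo-inositol                 AUC 0.980 (control-high) CI [0.878, 1.000]
```

And the correlation screen recovers the phenotype coupling built into the
generator (Myo-inositol coupled to immobility, target r = 0.59; here the
chronic-isolation group shift adds between-group signal on top):

```python
corr = mm.pearson_by_metabolite(tlog.subset_groups("CSIS", "Control"),
                                phenotype)
print(mm.correlation_filter(corr).tail(1).round(4))
```

```
                   r       p  degenerate
metabolite
Myo-inositol  0.7940  0.0007       False
```

The same stages are available as shell subcommands
(`metamark simulate | preprocess | univariate | plsda | roc | panel |
correlate | report`), all writing TSV with a commented provenance line,
and `mm.run_pipeline(...)` executes everything per comparison into one
results directory.

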