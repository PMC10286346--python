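# Methods

## Scope and data situation

The package re-implements the full phase-III computation of a
spondyloarthritis screening questionnaire's development: per-item
case–control screening, factorability diagnostics, principal-component
extraction with varimax rotation, reliability/validity-based item
reduction, merged-scale cutoff derivation, and ROC screening performance.
The development cohort's subject-level responses were never deposited.
Three printed results are nevertheless exactly recomputable, because their
inputs are themselves printed: applying the 0.70 retention rule to the
published per-component reliability table retains exactly components C1
and C2; merging their items gives an 11-item instrument; and the published
global reliability of 0.669 yields a referral cutoff of ⌊0.669 × 11⌋ = 7
positive answers. Everything else is validated behaviourally, on synthetic
cohorts that emulate the study's design.

## Synthetic cohort model

Each subject carries two latent traits, an axial burden and a peripheral
burden, drawn from a bivariate normal with unit variances, correlation ρ
(default 0.3) and group-specific mean shifts. An item tagged with a factor
responds positive when

    λ·T + √(1−λ²)·Z > τ,     T the subject's trait, Z ~ N(0,1),

and untagged items are pure noise (λ = 0). Because λ·T + √(1−λ²)·Z is
standard normal up to the group's mean shift, the threshold that yields a
target marginal prevalence π in a group with trait shift s is available in
closed form, τ = λs + Φ⁻¹(1−π), so every per-group item prevalence is
matched exactly in expectation regardless of the correlation structure.
Printed prevalences of 0% or 100% are clamped to 0.5% / 99.5% so
thresholds stay finite.

Default parameters reproduce the development design: groups of 50 / 150 /
200 with the printed age distributions (truncated-normal on [18, 95],
reflecting the ≥ 18 years inclusion rule), male fractions 0.56 / 0.287 /
0.58, and the 20 items' printed per-group "yes" fractions. Age at onset is
age minus an exponential lag (mean 4.3 years, matching the printed ~4-year
age-minus-onset gap); it is omitted for healthy subjects, for whom
"onset" is undefined. The 8 inflammatory-back/enthesitis items are tagged
axial and the 3 joint items peripheral, mirroring the two patterns the
validated instrument separates.

### Loadings: a deliberate trade-off

The loadings are generator parameters, not estimates; the published study
reports no correlation matrix to fit them to. They were fixed once, at
design time, against two competing requirements:

* strong loadings make the planted two-block structure easy for phi-based
  PCA to recover — phi correlations between binary items are attenuated
  far below the latent correlation, drastically so at skewed prevalences;
* near-unit loadings make a block behave like a single super-item, which
  fattens the upper tail of the control-group score distribution and
  degrades ROC discrimination of the summed score.

The defaults are 0.80 for tagged items and 0.98 for urethritis. With them,
the pipeline recovers the planted axial/peripheral partition in roughly
85% of seeds (the residual failures are almost entirely the urethritis
item: at a pooled prevalence of 2.5% — ten positives in 400 subjects — a
single chance co-occurrence with another rare item can form a spurious
doublet component that outbids its genuine block loading, which is
precisely the mechanism behind the published solution's own rare-item
doublet components C3–C6), and the merged scale separates cases from both
control groups with AUC > 0.9 in essentially every run. Pushing the
loadings toward 1 raises recovery only marginally while collapsing the
AUCs; lowering them improves nothing. One consequence is accepted rather
than hidden: the simulated C1 alpha (≈ 0.86) overshoots the printed 0.830,
and the simulated C2 alpha (≈ 0.63) undershoots the printed 0.708, which
sits exactly at the 0.70 retention floor — so on synthetic cohorts the
reliability filter usually keeps only the axial component. The printed
alphas are not reproducible anyway without the original data; the
published 11-item instrument is instead reproduced exactly from the
printed reliability table.

### What the generator does not emulate

No X-ray findings, HLA-B27, BASDAI/BASFI/BASMI, disease duration or SpA
subtypes; no item nonresponse (the file contract forbids missing
responses); no within-group heterogeneity beyond the two latent traits;
and no dependence among the untagged items, whereas real "noise" items
(family history, psoriasis, diarrhea) share infection- and
awareness-related background. Passing tests therefore show that the
pipeline's statistics are computed correctly and that it recovers planted
structure of realistic strength — not that the instrument itself would
validate in a new population.

## Statistical choices

* **Test selection.** The study names both Pearson's χ² and Fisher's exact
  test without a rule; Cochran's expected-count < 5 criterion decides, and
  the report's method column makes the choice auditable. The sparse rows
  (e.g. 2/50 vs 0/150) are only non-significant under the exact test; the
  Pearson statistic on those counts would be significant. This discrepancy
  is surfaced, not resolved.
* **"Discriminating" item.** Significant (p < 0.05, two-sided) versus at
  least one control group — the only reading consistent with the six
  items the study describes as non-discriminating. On the default
  generator 13/20 items discriminate; the printed per-item p-values
  support the same count, although the study's text says 14/20. The counts
  are internally inconsistent in print; the report states what its rules
  yield. No multiple-testing correction is applied (none is used in the
  study); a Bonferroni column is printed as supplementary information.
* **Correlations for PCA.** Pearson on 0/1 responses (phi), the classical
  SPSS workflow; a tetrachoric option exists behind a flag because binary
  items strictly violate PCA's continuity assumption. Pooled 400-subject
  matrix by default (a case–control discrimination instrument needs the
  pooled structure), restrictable by group.
* **Retention and rotation.** Kaiser eigenvalue > 1 by default, fixed-k
  override for reproducing a 6-component run. Varimax only — orthogonal
  rotation is what the study's methods specify, despite a stray mention of
  an oblique rotation in its results; communalities are preserved to 1e−8
  and each column's sign is fixed so its largest loading is positive.
  Variance shares are expressed over retained components ("common
  variance"), summing to 1.
* **Assignment.** Maximum |rotated loading| ≥ 0.36 (the printed C1
  threshold); the higher per-component thresholds quoted for C2–C6
  describe the observed solution and are not treated as rules. Ties within
  1e−9 go to the lower component index.
* **Validity columns.** The computation behind the printed
  convergent/discriminative validity values is not recoverable; they are
  implemented as multitrait scaling-success rates (corrected item–scale
  correlation ≥ 0.40 for convergence; corrected own-scale correlation
  strictly greater than each cross-scale correlation for discrimination),
  the framework whose "success" phrasing and value ranges match the
  printed table. This is a declared stand-in, validated by property: on
  planted two-block cohorts the block components score high and the
  leftover components fail.
* **Retention rule.** A component is excluded when *any* of alpha,
  convergent or discriminative validity falls below 0.70 (boundary
  inclusive). The study's conjunction is grammatically ambiguous; with the
  printed values both readings retain exactly C1 and C2, so the stricter
  rule is safe.
* **Global alpha and cutoff.** The published "adjusted" global alpha is
  implemented as the plain Cronbach's alpha of the merged scale (the
  standardized Spearman–Brown variant is also reported). The cutoff rounds
  down: 0.669 × 11 = 7.36 and the published rule is ≥ 7; ceil (→ 8) is
  available as a config option.
* **ROC.** Integer-cutoff sweep of "score ≥ k", k = 0..max+1; trapezoidal
  AUC (provably equal to Mann–Whitney concordance with ties at ½, checked
  to 1e−10). CIs via Hanley–McNeil by default — the classical
  nonparametric choice when no method is stated — with DeLong behind a
  flag. High score ⇒ case is fixed; an AUC below 0.5 is reported as-is.
  Predictive values use the sample's case:control composition; degenerate
  denominators yield flagged missing values, never crashes.

## Numerical notes

* Varimax: pairwise closed-form angle (atan2 of the quartic moments),
  sweeps until the criterion gain < 1e−6, 100-sweep cap with a
  non-convergence flag; Kaiser normalization on by default, rows with
  near-zero communality left unscaled.
* KMO rejects singular matrices (condition number > 1e12) and the exact
  identity (0/0); Bartlett requires n > p and positive-definiteness via
  the sign of the log-determinant.
* Zero-variance items get zero off-diagonal correlations and a degeneracy
  flag; an item constant in both compared groups screens as p = 1 with a
  `degenerate_constant` method tag.
* Tetrachoric correlations invert the bivariate-normal quadrant
  probability by Brent's method (xtol 1e−8), with a 0.5 continuity add
  for empty cells.
* All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global state. Identical configs produce
  byte-identical artifacts (timestamp aside).

## Problem sizes

The test and acceptance runs use the study-sized cohort (n = 400, 20
items) throughout; structure recovery is judged over 20 seeded runs, the
permutation null over 100 label shuffles, closed-form alpha recovery at
n = 2000, and the exact-test oracle over ~1000 enumerated tables. A full
suite plus the acceptance script completes in well under a minute on one
CPU.

## Known limitations

* The marginal calibration is exact in expectation only; at n = 50 the
  case group's realised prevalences wobble by ±0.06.
* Assignment of very rare items (pooled prevalence ≲ 3%) is intrinsically
  unstable under phi-based PCA at n = 400, as discussed above.
* The scaling-success implementation of the validity columns is one
  defensible reconstruction among several; its absolute values should not
  be compared digit-by-digit with the printed table.
* Printed performance figures that are internally inconsistent in the
  source (a single PPV of 74.0% across three different control mixes; a
  Se/Sp pair that matches no cutoff row) are deliberately not used as
  checks anywhere.
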