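# Methods

This note documents the statistical procedures the package implements, the
synthetic-data conditions it is calibrated against, and the design choices
made where more than one defensible convention exists.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The analysis chain

1. **Measurement.** Each adversity dimension is a reflective latent factor
   over ordinal indicator items.  Family threat uses a single factor over
   seven conflict items; deprivation a single factor over six socioeconomic
   indicators; family unpredictability a higher-order structure in which
   three first-order factors (primary-caregiver unpredictability,
   secondary-caregiver unpredictability, family disorder; 3+3+4 items) load
   on one second-order factor.  Items are standardized (reverse-scored items
   reflected first) and the model is estimated by maximum likelihood on the
   pairwise-complete correlation matrix, minimizing
   `F = ln|Σ(θ)| − ln|S| + tr(S·Σ(θ)⁻¹) − p` with the latent variance fixed
   at 1, so loadings are directly standardized.  Optimization is L-BFGS-B
   with analytic gradients, convergence declared at projected-gradient norm
   < 1e−6, up to five jittered restarts, uniquenesses floored at 1e−4 with a
   Heywood flag.  Fit indices follow the standard formulas (RMSEA with the
   `max(χ²−df,0)` numerator; CFI/TLI against the independence baseline;
   SRMR as the RMS residual correlation); a just-identified model reports
   RMSEA 0 and is flagged.  Factor scores are regression-method
   (`Λ'Σ⁻¹z`, second-order loadings `λ_j·γ_k` for the higher-order model),
   computed from the available-item submatrix when indicators are missing,
   and mean-centered at zero.

2. **Latent change.** Connectivity and symptom change are single-indicator
   latent change scores, i.e. the later minus the earlier observed value —
   the just-identified difference-score formulation.  Participants missing
   either timepoint are excluded from the change distribution and counted.

3. **Polynomial outcome models.** For each adversity × outcome × timepoint
   cell, symptom change is regressed on powers of the centered factor score
   plus covariates (sex, age, income; scanner optionally as fixed-effect
   dummies).  Point estimates are least squares; coefficient covariance is
   the CR1 cluster-robust sandwich over families,
   `(X'X)⁻¹(Σ_c X_c'e_c e_c'X_c)(X'X)⁻¹ · G/(G−1)·(n−1)/(n−k)`, which
   reduces exactly to HC1 when every cluster is a singleton.  Standardized
   coefficients are `β_p = b_p·SD(x^p)/SD(y)`.  Nested degrees are compared
   by plain likelihood-ratio test on profiled Gaussian likelihoods; the
   ladder retains the quadratic only if it beats the linear at α, and the
   cubic is compared against the last retained model.  A cubic is probed
   only when both the LRT and the cubic coefficient are significant.

4. **Hormesis probing.** Critical points are the closed-form roots of the
   derivative; the root with positive curvature (the risk minimum) is the
   hormetic vertex.  The statistical inflection `−b2/(3b3)` is reported but
   zone partitioning uses the *conceptual* inflection: the smallest
   `x > hormetic vertex` with `f(x) = f(x_ref)`, found by bracketed root
   finding (Brent, 1e−10).  Regions are half-open with ties to the
   lower-risk side: strengthening `x < hv`, buffering `hv ≤ x ≤ ci`,
   rising toxic `ci < x ≤ tv`, falling toxic `x > tv`; zones split at `ci`.
   Breakpoints are also reported in predictor-SD units (Z-equivalents).

5. **Moderation.** The full-sample model carries all polynomial-by-moderator
   products; the three interaction p-values join one Benjamini–Hochberg
   family spanning every moderation test in a pipeline run.  Probing uses
   (a) simple-slope cubics at −1 SD / mean / +1 SD of the moderator,
   (b) multi-group fits parceled by region (linear×linear) and zone
   (quadratic×linear) with Wald χ²(1) equality tests of interaction paths
   across disjoint groups, and (c) Johnson–Neyman boundaries, the real roots
   of `θ(w)² − t²_crit·Var θ(w)` with the variance taken from the robust
   covariance; the quadratic case probes the conditional effect at a fixed
   x (default its mean, where it reduces exactly to the linear case).  The
   area-of-significance count is the number of participants in a region
   whose moderator value falls in a significant interval.

## Synthetic-data conditions

The generator is the package's specification of the study conditions, with
ground truth recorded for recovery testing.

- Loadings: threat (.81, .46, .74, .59, .63, .74, .50); deprivation
  (.42, .76, .83, .57, .54, .18); unpredictability first-order
  (.38, .61, .54 | .46, .66, .59 | .83, .82, .48, .62) with higher-order
  (.89, .56, .58).  Items are continuous responses `λη + ε`,
  `Var ε = 1 − λ²`, discretized at fixed thresholds into five ordered
  categories (two for the binary marital-status item).  The analysis treats
  ordinal items as continuous; loading-recovery checks therefore run on the
  continuous responses (`item_scale="continuous"`), since coarse
  categorization attenuates Pearson correlations by design, and
  polychoric/weighted-least-squares estimation is out of scope.
- Outcome model: change scores follow
  `Σ_p (b_p + g_p·w_std)·x^p + covariates + family intercept + noise` with
  threat→internalizing (0, .15, .13, −.17) cubic, deprivation→externalizing
  (0, .22, −.02, −.07) cubic, unpredictability→externalizing (0, .20, 0, 0)
  purely linear, and the single moderated path g₃ = .10 on
  threat³×connectivity-change.  The moderator enters the generator
  standardized (per-SD units): the observed connectivity change has SD
  ≈ 0.055, and interaction coefficients of interest live on the
  standardized-moderator scale, matching two-step practice of forming
  products from standardized saved scores.
- Connectivity: baseline mean .30 (SD .10); latent change mean .25,
  variance .003; observed change = latent change + noise with variance
  `Var(Δ)·(1−r)/r` at reliability r (default .9).
- Clustering: every family has at least one member; the overflow joins
  random families (mostly singletons plus sibling pairs, ABCD-like).  The
  family random intercept carries `icc·σ²` of the outcome noise (default
  icc .10) — intercepts only, as no stronger structure is asserted for the
  clustering.
- Conventions where no empirical value exists: outcome-change and baseline
  noise SDs are 1 (documented convention, not an estimate); missingness is
  completely at random and defaults to 0 (it is exercised explicitly in
  tests); the T2 baseline is independent of adversity since the model is
  about change, not level.

What the generator does **not** emulate: skewed/floor-effect item and score
distributions, site-level (multi-scanner) hierarchy beyond a label column,
informative missingness, and measurement non-invariance.  Passing tests
therefore demonstrate correctness of the estimators and probing geometry
under the stated conditions, not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery and calibration checks use the sizes at which the conditions were
defined: n = 10,000 for measurement recovery, n = 8,000 for cubic and
moderation coefficient recovery (tolerances ±0.05 and ±0.04), 100/400-seed
LRT power and null-calibration loops, 200-seed null-FDR calibration, and
500 simulations of 500 families for robust-interval coverage.  The
curve-probe and Johnson–Neyman oracles are brute-force grids at step 1e−4.
Plain (not scaling-corrected) LRTs are used, with their type-I behaviour
verified by simulation rather than by a robust correction; missing rows are
dropped listwise in regressions.  Large-sample normal critical values are
the default for robust inference (a df-based refinement is available).

## Open design choices taken

- **Conceptual-inflection reference.** The reference exposure `x_ref`
  defaults to the 5th percentile of observed scores ("none to minimal
  adversity"); `fixed` and `statistical` policies are selectable because no
  single operational rule is canonical.  With a symmetric synthetic score
  distribution the 5th percentile can sit above the curve's local maximum
  (the left tail of a `b3 < 0` cubic rises steeply), in which case the
  probe falls back to the statistical inflection and flags it — real
  cohort scores, being right-skewed with a floor, rarely trigger this.
- **Wald comparisons across groups** assume independent (disjoint-family)
  groups; families spanning groups are detected and flagged rather than
  re-estimated jointly.
- **FDR family** is all moderation interaction p-values in one run — the
  widest defensible family short of enumerating analyses externally.
- **Separate regressions per outcome × timepoint** rather than one joint
  system: with saturated covariate structure the point estimates coincide,
  and residual covariance across equations is not modelled.
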