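# Methods

## Problem and model

Differential scanning calorimetry (DSC) of a biological fluid records the
excess heat capacity C_P(T) absorbed as its dissolved biomolecules unfold,
typically scanned from ~10 to 95 °C. The resulting denaturation profile
(thermogram) is a composition-weighted superposition of the unfolding
transitions of the fluid's protein/metabolite ensemble, so disease-related
compositional changes shift and reshape it. tlbkit implements a
classification chain that turns such a curve into a single diagnostic
score, built for the intracystic-fluid use case (non-mucinous vs mucinous
pancreatic cystic lesions, and benign vs malignant mucinous lesions) but
agnostic to the fluid.

The chain is:

1. **Baseline correction.** A straight line through the mean (T, C_P) of a
   pre-transition window (default 40–45 °C) and a post-transition window
   (default 90–95 °C) is subtracted. A linear chord is the minimal
   defensible baseline model: it is parameter-free, exactly testable (a
   purely linear input maps to zero), and leaves any curvature inside the
   transition region untouched. Whether a curvature correction should be
   layered on top is an open design point; only the chord is implemented.
2. **Regridding.** Piecewise-linear interpolation onto a uniform grid,
   40–95 °C at ΔT = 0.25 °C. Linear interpolation is monotone and
   parameter-free, and is checked against a brute-force two-point
   interpolation oracle. Grids are generated by index arithmetic
   (`t_min + k·dt`), never by accumulating the step, so the last grid point
   is exactly 95.00.
3. **Area normalization.** Division by the trapezoidal integral over the
   retained 40–95 °C span, removing concentration/amplitude scale; the
   output integrates to 1 within 1e-9 and the whole chain is invariant to
   positive rescaling of the raw signal. Normalization happens over the
   full retained span, *before* feature truncation, because scale should be
   estimated from the whole retained curve, not from the feature window.
4. **Per-degree truncation.** The normalized curve is point-sampled at the
   31 whole degrees 55…85 °C — the region where biofluid transitions
   concentrate — giving the feature vector. Point sampling (rather than
   per-degree averaging) is exactly reproducible and keeps the features on
   the interpolation grid; both endpoints are included.

### Temperature-pair (top-scoring-pairs) features

For a pair of feature temperatures (Ti, Tj), the binary indicator
1[C_P(Ti) > C_P(Tj)] encodes local shape. Indicators are invariant to any
sample-wise monotone rescaling, which is why pair features tolerate
residual normalization and baseline imperfections. Each unordered pair over
the 31-point grid (465 candidates; the grid is small, so no pre-filtering)
is scored by

- primary: |P̂(X_Ti > X_Tj | class 1) − P̂(X_Ti > X_Tj | class 0)|, the
  between-class difference of the empirical ordering frequencies;
- secondary (tie-breaker): |between-class difference of the mean
  within-sample rank difference rank(Ti) − rank(Tj)|.

Exact ties in raw values count as "not greater" (indicator 0),
a consistent strictly-greater convention that matters for synthetic data
with duplicated values; under this convention the primary score is
reversal-symmetric only for tie-free data, and the canonical stored
direction of a pair is the one whose signed frequency difference is larger
(floored at 0 in degenerate tie cases). Pairs are ranked by (primary desc,
secondary desc, lexicographic (Ti, Tj)); by default the top `k_max = 10`
*disjoint* pairs (each temperature used at most once, the classical kTSP
convention) feed the penalized fit, which decides the final model size.
Disjointness and `k_max` are configuration, not dogma.

### Penalized logistic score

On the indicator matrix Z ∈ {0,1}^(n×k) the model minimizes

    (1/n) Σ_s [log(1 + e^{η_s}) − y_s η_s] + λ‖β‖₁,  η_s = β₀ + z_sᵀβ,

with the intercept unpenalized. λ runs over 100 log-spaced values from
λ_max (= max_j |z_jᵀ(y − ȳ)|/n, the smallest λ with all coefficients zero)
down to 10⁻³·λ_max, and is chosen by stratified k-fold cross-validation of
the held-out binomial deviance, k = min(10, smallest class size) by
default (a one-standard-error rule and leave-one-out are options). The
returned coefficients are the penalized solution itself — no
post-selection refit — and zero-coefficient pairs are dropped. A sample's
score is β₀ + Σ β_k·indicator_k ∈ (−∞, ∞); the decision rule is the
score's sign, with exactly 0 assigned to the negative (lower-risk) class.

Numerics: the objective is solved through the standard β = β⁺ − β⁻
splitting, giving a smooth bound-constrained convex program solved by
projected quasi-Newton (L-BFGS-B) with warm starts down the λ path;
coordinates at the bound are exactly zero and coefficients below 1e-8 are
snapped to zero. The λ path is truncated once the training deviance per
observation falls below 0.01 (the fit is saturated; smaller λ only
inflates coefficients), and a truncated cross-validation path repeats its
last held-out deviance — the usual regularization-path convention. The
solver is verified against an exhaustive 2-D grid search of the penalized
objective (step 1e-3) on a small instance; that oracle runs without an
intercept because a third grid dimension at that resolution is
impractical, while the intercept-only limit is covered by the closed-form
prevalence check. Note that the count of nonzero coefficients along a
lasso path is non-increasing in λ for typical data but is not a theorem;
the suite checks it on a fixed seeded instance.

Two presets mirror the two clinical questions: `itlb1` trains on samples
with confirmed diagnoses and validates on the high-probability remainder;
`itlb2` trains on all labeled samples with no held-out set (appropriate
when the class of interest has too few samples to split).

### Evaluation

Confusion metrics (sensitivity, specificity, PPV, NPV, accuracy) are exact
ratios; undefined ratios (zero denominator) are reported as not-available,
never as 0; display rounding is to whole percent. AUC is the normalized
Mann–Whitney U (ties counted ½), checked against brute-force concordance
counting. The 95% CI is a class-stratified percentile bootstrap (2000
replicates, seeded) — assumption-light at n ≈ 20 and correctly degenerate
at (1.00, 1.00) under perfect separation; no claim is made that it matches
any particular analytic CI method. Group scores are compared with the
two-sided Wilcoxon rank-sum test: exact enumeration when the smaller group
has ≤ 12 observations and the pooled sample is tie-free, otherwise the
tie-corrected normal approximation without continuity correction (so
identical groups give p = 1 exactly); the conventional two-sided 0.05
threshold is reported alongside.

## Synthetic cohorts

The generator emulates biofluid thermograms as a sum of Gaussian
transition peaks plus a linear baseline and white noise:

    cp(T) = Σ_m A_m exp(−(T − Tm_m)²/(2σ_m²)) + slope·(T − 40) + ε.

Biological variability: per-sample midpoint jitter ~ N(0, 0.5 °C) and
amplitude factor ~ N(1, 0.1) truncated positive. Defaults: 20
samples/class, noise SD 0.02 (≈2% of peak height), baseline slope 0.002
a.u./°C, raw sampling at 0.1 °C (deliberately different from the 0.25 °C
analysis grid so interpolation is always exercised), and 60% of each class
flagged as confirmed — matching the confirmed share of a realistically
sized single-center cohort — so the confirmed-trains preset has a genuine
validation split. All randomness flows through one seeded generator per
cohort; the seed is recorded in each sample's metadata.

Three named recipes define the study conditions: `null` (identical peak
ensembles; no signal), `shifted-peak` (one transition shifted 66 → 70 °C;
the recovery benchmark, whose selected pairs should straddle the 68 °C
midpoint), and `envelope` (three transitions at 62/70/77 °C, widths
2.6/2.6/3.0 °C, class-dependent amplitude redistribution; widths chosen so
jittered samples keep at least two resolved maxima in 55–85 °C). Gaussian
peaks are a simplification of two-state van't Hoff excess-heat-capacity
shapes; the pipeline is rank-based and shape-agnostic, so peak shape is
immaterial to what the tests probe. What the synthetic cohorts do **not**
emulate: instrument artifacts (scan-rate dependence, feedback mode,
rescan drift), heavy-tailed or correlated noise, class-imbalanced cohorts,
and the real heterogeneity of intracystic fluid (inflammation, necrosis,
hemorrhage). Passing the synthetic benchmarks therefore demonstrates the
pipeline's statistical machinery, not clinical performance.

## Problem sizes and degenerate inputs

Benchmarks run at 20 samples/class with 25 seeds for null calibration and
50 for pair recovery — sizes chosen to keep the full suite comfortably
interactive while leaving the binomial noise on the reported rates small
relative to their acceptance bands. Degenerate inputs are first-class:
empty cohorts round-trip as header-only files; non-positive thermogram
area raises a normalization error (a failed scan); all-constant indicator
columns fall back to an intercept-only prevalence model with a warning;
an all-confirmed cohort yields an empty validation set with a warning; and
a model refuses to score features prepared on a different grid (grid hash
recorded in the model JSON).

## Known limitations

- The linear-chord baseline cannot remove curved instrument baselines.
- The bootstrap CI is percentile-based and can be optimistic at very small
  n; no DeLong variance estimation is provided.
- With heavily correlated indicator columns the lasso solution is not
  unique; the solver returns the symmetric solution, so reported
  coefficients should be interpreted jointly, not individually.
- Synthetic recipes are not calibrated to any real fluid's transition
  temperatures or amplitudes; they are controlled test beds only.
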