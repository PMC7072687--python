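# Methods

This note records the statistical models implemented in `readerstudy`, the
defaults and why they were chosen, the numerical choices, and what the
synthetic-data layer does and does not emulate.

## Data model

A rating study is a dense `(modality t, reader r, case c)` score array on
the 0–100 scale with per-case binary truth (0 benign, 1 malignant). The
design is fully crossed; a missing cell is an error, never imputed, because
the paired two-read design the package targets has every reader scoring
every case under both conditions. Scores are stored as reals: the 0–100
scale admits decimals and validation checks range only. Cases are
nodule-level observations; no patient-level clustering term is modelled.
Truth classes must each contain at least two cases so every leave-one-out
metric is defined.

Reader experience splits assign exactly `threshold` years (default 10) to
the senior group. The boundary is documented because "junior < 10 ≤ senior"
is a convention: panels whose experience ranges avoid the threshold (e.g.
2–9 vs 14–31 years) are unaffected by it.

## ROC machinery

*Empirical / Wilcoxon.* Operating points follow "positive if score ≥
threshold"; the Wilcoxon AUC is computed from midranks and equals both the
normalised Mann–Whitney U (ties counting half) and the trapezoidal area
under the empirical points, an identity the tests verify against direct
pair enumeration.

*Binormal fit.* `fit_binormal` maximises the Dorfman–Alf categorical
likelihood: benign latent N(0,1), malignant N(a/b, 1/b²), cutpoints
estimated jointly. Choices:

- Ratings with more than `max_bins` (default 20) distinct values are
  quantile-binned on the pooled distribution; empty categories are merged.
- Parameters are transformed (log b; log cutpoint increments) to enforce
  b > 0 and cutpoint ordering; optimisation is L-BFGS-B with three slope
  starts b ∈ {0.5, 1, 2} and the intercept started from the Wilcoxon AUC.
  Convergence tolerance 1e−12 on the objective.
- Degenerate data: on perfect class separation or optimiser failure, a
  half-count continuity correction is added to the four extreme category
  cells and the model refit; if that also fails the returned curve is
  b = 1, a = √2·Φ⁻¹(Wilcoxon AUC). Either remedy reports
  `converged=False` and names itself in `fallback`, so downstream reports
  can flag affected readers.
- The conventional (unconstrained) binormal model is fitted, not the
  "proper" likelihood-ratio variant; the two differ only where the
  conventional fit produces non-concave hooks near the corners, which is
  immaterial at the operating regions summarised here (FPF ≤ 0.3 and the
  95% operating points).

Partial AUC integrates the fitted TPF(FPF) by adaptive quadrature
(absolute tolerance 1e−10); Se@Sp and Sp@Se are the closed forms
Φ(a + b·Φ⁻¹(1−spec)) and 1 − Φ((Φ⁻¹(sens) − a)/b).

*Estimator duality.* The DBM modality comparison uses the Wilcoxon AUC as
its accuracy metric (standard DBM practice: it is fast, unbiased under the
jackknife identity, and free of fit failures), while curve-shape metrics
(pAUC, Se@Sp, Sp@Se) come from per-reader binormal fits averaged over
readers. Reports state which estimator produced each table.

## DBM modality test

Pseudovalues Yᵢⱼₖ = c·θ̂ᵢⱼ − (c−1)·θ̂ᵢⱼ₍ₖ₎ are computed in O(n₀·n₁) per
reader-modality by updating the Mann–Whitney win matrix row/column sums
rather than recomputing each leave-one-out AUC. For the Wilcoxon metric
the case-mean of the pseudovalues equals θ̂ᵢⱼ exactly (U-statistics are
jackknife-unbiased); the suite asserts this to 1e−10.

The three-way ANOVA uses the standard one-observation-per-cell crossed
decomposition; the seven mean squares satisfy the sum-of-squares identity
to 1e−10 by construction. The modality test is Hillis-corrected by
default:

    F = MS(T) / D,  D = MS(TR) + max(MS(TC) − MS(TRC), 0),
    ndf = t − 1,    ddf = D² / (MS(TR)² / ((t−1)(r−1))).

The original DBM form (untruncated denominator, ddf = (t−1)(r−1)(c−1)) is
available with `hillis=False` because p-values differ and users comparing
against older software need the distinction to be explicit. When every
relevant mean square is zero the test reports p = 1 with a "no
variability" flag rather than 0/0.

Interval estimates reuse the test's denominator: the two-modality
difference CI is diff ± t_{ddf,0.975}·√(2D/(rc)). Per-modality CIs use the
Hillis single-treatment form from the within-modality reader×case
pseudovalue ANOVA: variance (MS(R) + max(MS(C) − MS(RC), 0))/(rc) with the
analogous df. The original report format this mirrors does not state its
CI construction; this package's choice is labelled in its output.

Per-reader modality tests are the single-reader special case: a paired
one-sample t test (c − 1 df) on the per-case pseudovalue differences.
Experience-subgroup comparisons run the full DBM pipeline per group; the
between-group contrast is Welch's t test on per-reader AUC improvements.
Both are package choices where the mirrored report format names no method,
and both are labelled in output.

Power is estimated by Monte Carlo — simulate, test, count rejections —
rather than a noncentral-F approximation, because the variance components
a closed form needs are exactly what a planning user typically lacks; the
simulator stands in for pilot data. The binomial standard error is
returned alongside the estimate.

## Interobserver variability

Per-case spread is the sample SD (divisor r − 1) of the r reader scores;
with the panel sizes this package targets the printed-precision difference
from the population SD is negligible, but the convention is fixed and
documented. Averages over all/benign/malignant case subsets satisfy the
exact weighted decomposition avg(all) = (n₀·avg(benign) +
n₁·avg(malignant))/c, which the tests use as an internal consistency
check. Modality comparisons are paired t tests over cases (matching the
paired per-case structure), with a Wilcoxon signed-rank alternative; a
zero-variance difference vector returns p = 1 with a degeneracy flag.
Class-conditional mean scores are compared the same way on per-case
reader means.

## Segmentation match ratio

Contours are closed polylines in millimetres (≥ 3 vertices, no repeated
consecutive vertices; open polylines are rejected, not silently closed).
"Nearest point on the locus" is interpreted as the continuous curve:
point-to-segment distance over all edges (computed with shapely), with a
vertex-only mode retained for sensitivity analysis since vertex-sampled
implementations also exist. The metric is directional — physician vertices
against the software locus — and depends on vertex sampling density, so
results record vertex counts.

Category boundaries: excellent requires ratio = 1 within 1e−12 (100% read
literally); exactly 0.70 classifies as satisfactory (the closed lower
bound must be assigned somewhere, and the category is defined by reaching
70%). The benign-vs-malignant comparison of successful-segmentation
fractions is a Pearson chi-square without continuity correction (Yates
selectable). On published cross-tab counts of 135/30 successful/poor
benign vs 88/12 malignant this test gives p ≈ 0.17; a smaller published
p-value for the same table is only obtainable from the underlying
continuous ratios, which a count-level test cannot reproduce — the output
therefore names the test it ran.

## Synthetic data

*Ratings.* The simulator is a deliberately simplified Roe–Metz model with
a single reader-skill term: latent
Z = (δᵢ + τRᵢⱼ)·sₖ + Cₖ + RCⱼₖ + εᵢⱼₖ, with case and reader×case effects
shared across modalities (producing the positive within-case correlation
of a paired design) and modality-specific noise the only decorrelating
term. The simplification is intentional: it admits the closed form
E[AUC] = Φ(δ/√(2 + σ²_τR)), which turns the whole simulate→analyse
pipeline into a testable parameter-recovery problem. The full
eight-component Roe–Metz model adds realism the tests could not check.

Defaults emulate the target study's shape: 19 readers, 165 benign + 100
malignant cases, two modalities with δ calibrated to expected AUCs 0.728
and 0.792, σ²_τR = 0.04 (reader AUC SD ≈ 0.03 at these operating points),
and within-class variance split 0.6/0.2/0.2 between case, reader×case and
noise — a case-dominated structure typical of reported MRMC variance
analyses. Scores are clamp(round(50 + 20·Z), 0, 100): the gain of 20
points per latent unit keeps ~99% of benign scores inside the scale while
still exercising the floor/ceiling effects bounded scales show in
practice. Truth-class latent variances are equal; an unequal-variance
extension is deferred.

What the simulator does *not* emulate: real reader idiosyncrasies in scale
usage (some readers compress into the low range), case-difficulty
heterogeneity beyond a single Gaussian case effect, modality-dependent
variability reduction (the with-CAD decrease in interobserver SD seen in
real data is not built into the default generator), and any image content.
Passing calibration tests therefore show the *inference machinery* is
correct under a plausible data-generating process, not that real studies
satisfy that process. Note the score map's discretisation is not fully
AUC-neutral: doubling the slope to 40 clamps enough scores to shift the
mean AUC by ≈ 0.006, which is why the invariance check bounds the shift
at 0.01 rather than 0.

*Contours.* Physician contour: a circle (default radius 10 mm, 180
vertices). Software contour: the same circle with smoothed per-vertex
radial Gaussian noise plus a constant radial offset; candidates with
non-positive radii or self-intersections are resampled (bounded retries).
Truth labels are Bernoulli at the 100/265 malignancy prevalence of the
emulated study set. The generator spans all three match categories as the
offset crosses the 1 mm tolerance.

Determinism: every generator draws from one `numpy.random.default_rng`
seeded from its config; identical configs give bit-identical output.

## Problem sizes in the checks

The statistical acceptance checks run at the study's own scale: null
calibration uses 1000 simulated studies (19×265×2), AUC recovery 200, and
the power comparison 500 per design point — sizes at which the binomial
and Monte-Carlo errors quoted alongside each check are small relative to
the tolerances asserted. The whole suite runs in well under a minute on a
single CPU because the jackknife is computed by win-matrix updates rather
than naive leave-one-out recomputation.

## Known limitations

- Only the fully crossed paired design is supported: no split-plot,
  unpaired, or hierarchical (patient-clustered) variants, and a single
  random-reader covariance structure (the DBM one). The
  Obuchowski–Rockette correlated-error formulation is not implemented.
- The binormal fit is the conventional model; strictly proper (concave)
  curves are not enforced.
- Confidence bands on individual ROC curves and covariate-adjusted ROC
  regression are out of scope.
- The contour metric is 2D and point-based; pixel-mask overlap metrics
  (Dice/Jaccard) and 3D surfaces are out of scope.
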