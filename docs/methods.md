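# Methods

## The measurement model

The FHOC size is defined as the maximum transverse diameter of the ossified
capital femoral epiphysis: the linear distance between the medial margin and
the outermost lateral point of the ossification center on an AP radiograph.
On a segmentation mask those two cortical landmarks are the horizontal
extremes of the foreground region, so "transverse" is anchored to the image
column axis, not to the shape's own principal axis — rotating an anisotropic
shape by 90° genuinely changes what is measured, and the test suite asserts
this. A maximum-Feret-diameter definition was considered and rejected: it
ignores the medial/lateral naming of the landmarks and would measure oblique
chords that no reader would call a transverse diameter.

Measurement runs in three steps on a binary mask with isotropic spacing
(anisotropic inputs are rejected rather than silently averaged):

1. **Component filtering.** Only the largest 8-connected component is kept,
   for robustness to speckle in predicted masks; the number of discarded
   components is reported. An empty mask raises a *no ossification center*
   error rather than returning zero — absence of the FHOC is clinically
   meaningful in infants (the center appears at about 4 months in half of
   children). Equal-area ties are broken toward the component whose first
   pixel in row-major scan order comes first; arbitrary but deterministic.
2. **Landmark detection.** Candidate pixels are those attaining the minimal
   and maximal column index. Within each extreme column the landmark row is
   the *lower median* of the candidate rows: for a convex boundary the
   foreground span within the extreme column is centered on the
   vertical-tangent point, so the median tracks the point the extreme chord
   actually touches. (A tie-break toward the row nearest the global centroid
   was tried first and discarded: on steeply rotated elongated ellipses it
   systematically picks the inner end of the span and distorted the measured
   chord by up to 6 px in benchmarks; the median rule brought the worst case
   below 2 px.) The landmark column is then pushed half a pixel outward,
   because pixel centers sit at integer coordinates and the physical boundary
   lies half a pixel beyond the outermost center. A single-column mask
   degenerates to two equal landmarks and size zero.
3. **Size.** Euclidean distance between the two landmarks × spacing (mm).

Coordinates are (row, col), 0-based, row 0 at top, pixel centers at integers.
Side semantics: on a patient's *right* hip the image-left point is the
lateral cortex; on the *left* hip it is the medial margin; with side unknown
the labels mean image-left/image-right.

## Evaluation metrics

Dice is 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty. The
Hausdorff distance is the *exact* (100th-percentile) symmetric Hausdorff
distance between boundary point sets, where a boundary pixel is a foreground
pixel with at least one 4-neighbor background pixel (image borders count as
background). The exact variant was chosen over HD95 because it admits a
brute-force oracle; if robustness to single-pixel outliers matters, compute
HD on filtered masks. Landmark accuracy is summarized by the mean radial
error (MRE, mm) and the successful detection rate SDR(t) = percentage of
cases with radial error ≤ t, at thresholds {1, 2, 2.5, 3, 4} mm.

## Agreement statistics

Differences are always **automatic − reference**, so positive Bland–Altman
bias means the automatic method overestimates; output headers state this.

* **CCC** (Lin): 2·cov(x,y) / (var x + var y + (x̄ − ȳ)²) with population
  (1/n) moments; the 95 % CI uses the Fisher z-transform with Lin's
  asymptotic variance. CCC ≤ r always (equality iff means and variances
  agree), and the suite property-tests this inequality.
* **Pearson r**: CI = tanh(atanh r ± 1.96/√(n−3)).
* **MAE/RMSE**: point estimates plus nonparametric case-resampling bootstrap
  percentile CIs (B = 2000 by default, seeded and bit-reproducible). A
  bootstrap was chosen because no distributional form for the absolute
  errors is assumed; B < 100 triggers a logged warning.
* **Bland–Altman**: bias ± 1.96·sd(diff) with the n−1 sample sd and the
  fixed normal multiplier 1.96 (not t-based), the conventional choice;
  proportional bias is the least-squares slope of differences on pairwise
  means with its two-sided p.
* **Paired t** and **Fisher Z** (two-sided normal p on
  (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))) complete the battery. For
  between-group Fisher Z the group size is the number of hips (rows), not
  children — bilateral measurements are treated as the sampling unit
  throughout.
* **Stratification**: by sex, side, age bin, or their product (the 12×2
  age-sex grid); strata with n < 3 are reported as insufficient, never
  silently dropped.

## Growth-chart model

For each sex, quantile curves of size vs age are polynomials fitted by
minimizing the pinball loss Σ ρ_τ(yᵢ − p(aᵢ)) subject to p′(a) ≥ 0 at a grid
of ages — the standard LP surrogate for functional monotonicity, which is
the biological constraint (FHOC size does not shrink with age in healthy
children). The problem is solved exactly with HiGHS via `scipy.optimize.linprog`
(primal/dual feasibility tolerance 1e−7; fully deterministic, no randomness
anywhere in fitting). Ages are affinely rescaled to [0, 1] before building
the Vandermonde basis, which keeps the LP well conditioned and leaves the
monotonicity constraint unchanged.

Defaults and why:

* **degree 3** — the published percentile anchors lie on cubics to within
  0.002 mm, and visual growth-curve curvature (fast infant growth, later
  deceleration) needs at least a cubic; degree is a config knob.
* **quantile levels** {0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95}.
* **constraint grid step 0.25 y**; the suite verifies monotonicity on a 5×
  finer grid (0.05 y), since a cubic whose derivative is nonnegative on a
  grid could in principle dip between nodes.
* **non-crossing** is enforced by post-fit rearrangement — sorting the
  predicted quantiles at each evaluation age. Rearrangement is
  order-preserving, never worsens fit, and is much simpler than jointly
  constrained fitting; at these sample sizes crossings are rare and tiny.
* **reference range 0.5–11 years**; evaluation outside the fitted domain is
  an error — reference values are never extrapolated.
* **per-hip rows** (two per child) are the default fitting unit, matching
  the bilateral framing of the agreement analysis; per-child averaging is
  available as an option.

Downstream products: percentile tables at integer ages; a clinical lookup
that places one measurement by monotone interpolation across the seven
fitted quantiles (values outside the 5th–95th band are flagged `<5` / `>95`,
not extrapolated); adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with p = degree,
computed from *median-curve* residuals (which curve the R² should describe
is genuinely open; the median is the only symmetric-loss curve in the set);
and per-age-bin MAE/RMSE of the median curve with bootstrap CIs. Bin errors
are in-sample residuals and labeled as such; empty bins report missing
values, not zeros.

## Synthetic data

The generator replaces the private radiograph cohort and defines the study
conditions for every test.

**Masks** are rotated ellipses rasterized at pixel centers, with an optional
inferior crescent cut (a fraction of the vertical extent removed, mimicking
partial ossification of the epiphysis) and optional smooth periodic boundary
noise (a 5-harmonic random Fourier perturbation scaled to a target sd in
pixels). The true extreme-column landmarks and diameter are computed
analytically from the noiseless geometry, so measurement accuracy can be
asserted against closed-form truth. What these masks do *not* emulate:
radiographic texture, over/under-segmentation of real predictors, contact
with the acetabulum, and non-elliptical pathology (DDH, LCP) — so passing
tests certify the *measurement geometry*, not segmentation robustness on
real radiographs.

**Cohorts** draw ages uniformly within twelve bins (0.5–0.75, 0.75–1, 1–2,
…, 10–11 years; infancy split finer because growth is fastest there), both
sexes, bilateral. The per-age size distribution is a **two-piece (split)
normal** centered on the monotone PCHIP interpolation of the published
median anchors, with half-widths σ_lo = (q50 − q5)/z₀.₉₅ below and
σ_hi = (q95 − q50)/z₀.₉₅ above the median (z₀.₉₅ = 1.6449). The split form
is needed because the anchor tables are mildly skewed — at age 11 the lower
half-spread exceeds the upper by up to 2.8 mm — and a symmetric normal with
σ = (q95 − q5)/(2z₀.₉₅) would shift both tails' true quantiles away from the
anchors by half the skew (up to 1.4 mm), i.e. it could not reproduce the
table it is anchored to. For symmetric anchors the two halves coincide with
that σ. Left/right sizes share a bivariate standard normal (correlation
0.98 by default, reflecting the near-identical left/right age correlations
reported for healthy hips) pushed through the same quantile transform;
draws are floored at 0.01 mm. The per-age distributional *shape* is a
modeling stand-in, not an empirical claim about any real cohort; only the
three anchor quantiles are data-driven.

**Reader simulation** adds `reference = size + bias + N(0, sd)` per row;
default sd 0.96 mm, which puts Bland–Altman 95 % LoA near ±1.9 mm, the
magnitude reported for expert AI-vs-reader agreement on this measurement;
default bias 0.

All randomness flows from explicit integer seeds; the pipeline derives one
independent sub-seed per stage by hashing the stage name, so stages can be
re-run in isolation.

## Problem sizes used in tests and the acceptance script

Anchor-recovery fits use 250 children per sex per bin (3000 per sex, 6000
hips per sex); at that size the worst-over-ages deviation of the fitted
median from the anchors is typically ~0.3 mm and that of the fitted 5th
percentile ~0.6 mm, driven by sampling noise that concentrates at the
domain edges (ages 0.5 and 11), where tail quantiles of a polynomial fit
are hardest to pin down. The agreement simulation uses 600 children / 1200 hips — the
scale of the reference test set — and 200 replicates for the qualitative
pattern check. Measurement accuracy is asserted over 200 random shapes at
0.2 mm spacing on 192² images.

## Known limitations

* The landmark rule is a reconstruction from the landmark definitions
  (medial margin / outermost lateral point); the original post-processing
  algorithm it stands in for is not public, and no claim of per-pixel
  equivalence is made.
* Exact Hausdorff (not HD95) is reported; the two differ on masks with
  isolated boundary outliers.
* Growth charts use chronological age only; bone age, weight, and skeletal
  maturity staging are out of scope, as are LMS-style (Cole) reference
  methods and longitudinal per-child modeling.
* Bin-level prediction errors are in-sample; no train/test split is
  performed on synthetic cohorts.
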