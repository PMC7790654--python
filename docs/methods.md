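# Methods

This note records the statistical model, the defaults and why they are set
where they are, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know about.

## Point-process model

Presence-only records are modelled as an inhomogeneous Poisson process
(IPP) in continuous space: the data carry information about *where*
intensity is relatively high, not about absences. With features
z(x) — min–max scaled predictors and their squares, computed from
calibration bounds and clamped to [0, 1] on projection data — the
log-intensity is η(x) = β'z(x) and β minimizes

    f(β) = −(1/n) Σ_pres η(x_i) + log Σ_bg e^{η(z_j)} + Σ_k λ_k |β_k|.

No intercept is needed: it cancels exactly between the two data terms. The
background sum is a Monte-Carlo quadrature of the intensity integral over
the accessible area; the default background is 10,000 uniformly sampled
unmasked cells (without replacement when the grid allows), a size at which
the normalizer is stable for regression-type presence-only estimators.

**Penalties.** λ_k = rm · Λ_class(n) · √(var_k(presences)/n). The
per-class base schedule Λ is the maxent default, linearly interpolated on
the presence count n (linear features: 1.0 at n ≤ 10 falling to 0.05 at
n ≥ 100; quadratic: 1.3 at n ≤ 10 through 0.8 at 17 and 0.5 at 30 to 0.05
at n ≥ 100). The regularization multiplier rm is the single tuned knob,
over {1, 1.5, …, 5}.

**Optimizer.** FISTA (proximal gradient with Nesterov momentum) with
backtracking line search, momentum restarts on objective increase, and a
step that re-grows between iterations. Convergence is declared when the
penalized objective changes by less than 10⁻⁵ (configurable) between
iterations, capped at 5,000 iterations; both the flag and the iteration
count are stored on the model. The same estimator is the W → ∞ limit of
logistic regression with background weight W (presences weight 1, free
intercept, identical per-feature penalties scaled per presence). That route
is implemented as `fit_iwlr` — solved by the split-variable (β = u − v)
smooth reformulation under L-BFGS-B, because FISTA converges poorly on the
ill-conditioned logistic surface — and serves purely as a cross-check: its
finite-weight bias is O(n/W), ~10⁻³ at W = 100 and ~10⁻⁵ at W = 10⁴ on
200-cell instances, which is what the equivalence tests verify.

**Outputs.** `raw` = e^η/Z with Z the stored background normalizer (raw
sums to 1 over the calibration background); `cloglog` = 1 − exp(−e^H·raw)
with H the entropy of raw over the background. With all-zero coefficients
every cell gets cloglog 1 − e⁻¹ ≈ 0.632 exactly — a useful identity the
tests pin to 10⁻¹².

**Model selection.** AICc = 2K − 2 logL + 2K(K+1)/(n−K−1), with K the
number of *nonzero* coefficients and logL computed from raw re-standardized
to sum to 1 over all supplied grid cells (the Warren–Seifert convention; the
criterion name alone does not fix these choices, so they are stated here).
Candidates with n − K − 1 ≤ 0 are flagged invalid rather than raising. Ties
break toward fewer nonzero coefficients, then smaller rm. Cross-validation
uses the nested-checkerboard ("checkerboard2") partition: a fine coloring
over blocks of agg1 cells and a coarse one over agg1·agg2 cells combine
into 4 spatial folds (fold = fine + 2·coarse + 1); each fold in turn is
held out, models are trained on the remaining presences against the full
background, and test AUC / omission rates are averaged over nonempty folds.
The construction yields exactly 4 folds by design; a seeded random k-fold
split is available through the evaluation utilities where a different fold
count is wanted.

**Variable importance.** Permutation importance is the drop in training AUC
after permuting one predictor across presences + background (repeats
averaged, normalized to 100%). Jackknife gain refits with each predictor
excluded and alone, reporting regularized training gain = null objective −
fitted penalized objective. Percent-contribution-style path attributions
are optimizer-dependent by nature and are not given beyond these two.

## Validation metrics

- **AUC** is the exact Mann–Whitney statistic via midranks
  (P(pos > neg) + ½P(tie)).
- **Thresholds**: MTP = min training presence score; 10TP = 10th percentile
  with linear interpolation between order statistics (the quantile
  convention is configurable; omission uses strict `<`, so MTP training
  omission is 0 by construction).
- **Partial ROC**: per bootstrap replicate (default 1,000 replicates on 50%
  resamples), the curve of (proportion of all cells ≥ t, test sensitivity
  at t) is restricted to sensitivity ≥ 1 − E (E = 5%); the ratio is the
  trapezoidal area under that curve over the area under the 1:1 null line
  on the same x-interval. A random model gives 1, a perfect one approaches
  2; with E = 1 the ratio reduces to 2·AUC, which the tests exploit.
  Thresholds are the unique cell scores, quantile-capped at 1,001 points.
- **Continuous Boyce Index**: 101 windows of width 10% of the background
  score range, spanning it; per window F = (presence share)/(background
  share), windows with zero background mass dropped, CBI = Spearman ρ(F,
  window center); undefined (None) below 3 usable windows. CBI is exactly
  invariant under affine score maps (windows rescale with the scores) but
  only approximately under general monotone maps, since windows are
  equal-width on the score scale. A *random* model's CBI is zero only in
  expectation: overlapping windows share samples, so single draws scatter
  widely (|CBI| up to ~0.6 even with 2·10⁴ presences); tests therefore
  check the mean over seeds. The cross-validated variant splits presences
  into 5 seeded folds and averages the per-fold (20% hold-out) CBI.

## Geography

Suitable area sums exact spherical quadrilateral areas
R²·Δλ·(sin φ_top − sin φ_bottom) using cell *edge* latitudes (R = 6,371 km);
the global 1° grid then recovers 4πR² to machine precision. Polygon (MCP /
extent-of-occurrence) edges are straight lines in lon/lat; their spherical
area is computed exactly by densifying edges and taking the shoelace area in
the cylindrical equal-area plane (x = λ, y = sin φ) × R². An optional land
mask restricts EOO to the summed area of land cells whose centers fall
inside the hull — no coastline is bundled; studies supply their own.

## ENFA

Predictors are standardized to zero mean / unit variance over a random
background sample (default 100,000 cells; all cells when the grid is
smaller). Occupied cells are weighted by their occurrence counts, so exact
duplication of records changes nothing, and the *unthinned* occurrence set
is the right input — ENFA measures conditions at presences directly, so
spatial autocorrelation is not the threat it is to the fitted model.
Marginality m is the weighted mean of standardized occupied values;
M = ‖m‖ (the unscaled modern convention; the classical /1.96 scaling is an
option). The first factor is m itself with ratio λ₁ =
(u'R_g u)/(u'R_s u); subsequent factors maximize that generalized Rayleigh
quotient subject to R_s-orthogonality to earlier factors, solved as a
symmetric-definite eigenproblem on the R_s-orthogonal complement basis
(null space of (R_s m)'). S = √(mean λ) over all P axes ("sum" variant
exposed); variance shares are each axis's percentage of total eigenvalue
mass. A singular occupied-covariance raises with its condition number.
λ₂ is verified against direct SLSQP maximization of the constrained
quotient to 10⁻⁶ for P ∈ {2, 3}.

## Projection, overlap, stability

Projection reuses the stored calibration bounds and normalizers; features
outside [0, 1] are clamped and the clamp fraction logged (heavy clamping
signals extrapolation). Period ensembles are cell-wise means (sums
available); nodata propagates. Schoener's D normalizes both surfaces to sum
to 1 over the shared unmasked cells and returns 1 − ½Σ|p − q|; the surface
supplied (cloglog by default in the pipeline) is what gets normalized, and
an all-zero surface yields an undefined (None) overlap. Stability stacks
the current binary map with the past ones: stable iff suitable now and in
every past period; colonizable iff suitable now but not in every past
period; unstable iff suitable only in the past; absence otherwise. Codes
(absence −2, colonizable −0.5, stable 1, unstable 2) follow the convention
that −2…1 runs from never- to always-suitable with 2 flagging past-only
suitability; the raw (current, past-fraction) layers are emitted alongside
the class raster so any alternative recode is derivable downstream.

## Synthetic data

The generator emulates a bioclimatic predictor stack and a presence-only
survey: white noise mixed through the Cholesky factor of a target
correlation matrix (cross-layer correlation), Gaussian-blurred layer-wise
(spatial autocorrelation, which the blur preserves across layers), each
layer re-standardized; intensity exp(Σ βL z + βQ z²) normalized over
unmasked cells; presences cell-multinomial with uniform within-cell jitter
(points must not sit on cell centers, or thinning tests would degenerate).
Bundled defaults — 100 × 100 cells of 2.5′, 3 layers, blur scale 5 cells,
500 presences, a unimodal surface (βL = (1, 0.6, 0), βQ = (−0.8, 0, 0)) —
give presence counts and predictor smoothness of the same order as a
thinned continental occurrence compilation on a coarse climate grid, at a
size every stage completes in seconds. The generator does *not* emulate:
observation bias fields (thinning is exercised by the sampler's natural
clustering, not by a bias model), real bioclimatic units or their physical
cross-dependencies, nodata coastlines (masks can be injected), or temporal
error in paleo layers (past periods are constructed shifts of one predictor
plus small circulation-model jitter). Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated generative
model — not robustness to survey bias or predictor misspecification in real
data.

## Reproducibility and numerics

One global seed expands through `numpy` SeedSequence into per-stage seeds
(all < 2³¹), recorded in every report; reports contain no paths or
timestamps and serialize with sorted keys, so identical configurations are
byte-identical. Stage artifacts are cached under the output directory with
a config hash; full-precision CSV round-trips (`%.17g` +
`float_precision="round_trip"`) keep resumed runs bit-identical to fresh
ones. Degenerate inputs fail loudly and early: constant predictors are
named in the error, non-PSD correlation targets report the offending
eigenvalue, all-masked grids and empty cleaned occurrence sets raise.

## Known limitations

- Feature classes are linear and quadratic only (hinge/product/threshold
  features, MESS-style extrapolation maps and landcover/human predictors
  are out of scope).
- The thinning heuristic guarantees feasibility, not optimality; at the
  default 100 trials it matches the exhaustive maximum on ≥ 95% of small
  random instances, and cardinality — not the identity of retained
  points — is the contract.
- AICc for presence-only models is a pragmatic ranking device; its
  likelihood is conditional on the grid standardization described above.
- Areas assume a spherical Earth (R = 6,371 km); ellipsoidal corrections
  (~0.3%) are ignored.
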