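# Methods

## Point eccentricity and weighting

For an ellipse with semi-axes `a ≥ b > 0` the eccentricity is
`ε = √(a²−b²)/a ∈ [0, 1)`. A data point `X_s` is assigned

    ξ_s = ε · d_a / (d_a + d_b)

with `d_a`, `d_b` its orthogonal distances to the minor- and major-axis
*lines* in the ellipse's own frame. Two readings of this quantity are
conceivable (a product, or ε evaluated at a rescaled argument); the product
form is adopted because, under uniform parametric-angle sampling, it
reproduces the established sector means for the b/a = 0.32 reference shape
(0.792539 … 0.936820 across the five standard sectors) to a few × 10⁻⁴,
which we verified by quadrature. ξ depends only on the *direction* of the
point's offset from the center, lies in `[0, ε]`, and is defined as 0 at the
exact center (the limit along the minor axis; the choice affects nothing at
measure zero).

Weights are `w_s = exp(ξ_s) ∈ [1, e]`, normalized to `W_s = w_s/Σw`. The
exponential keeps the dynamic range mild (at most a factor e between the
least and most eccentric point), so the augmentation is a gentle
re-balancing rather than a hard re-weighting.

ξ needs an axis estimate. In synthetic benchmarks the generating ellipse is
used directly; on real data either an ensemble mean of several fitters'
parameters (orientation averaged as a direction modulo π) or a first pass of
a single fitter serves. The weighting is insensitive to modest estimate
errors: a 5% perturbation of center, axes and orientation moves ξ by well
under 0.05 median on sector data whose working ξ scale is ≈ 0.8, and
preserves the weight ranking almost perfectly.

## The augmentation resampler

Systematic resampling over the cumulative weights `c_s = Σ_{k≤s} W_k` with
step `1/T`, `T = ⌊1/min W_s⌋` (≥ S since min W ≤ 1/S; capped at 10·S as a
guard for alternative weight functions — with exp(ξ) weights the uncapped
T never exceeds e·S). The traversal starts at `μ₁ = 1/T` (the deterministic
choice; starting at 0 would duplicate the first point exactly). Each
traversal step landing in interval s contributes one output point: the
original `X_s`, plus — for additional steps — points linearly interpolated
between `X_s` and its angular predecessor at equally spaced fractions.

Invariants: every original point is retained; per-interval output counts
match the allocation `T·W_s` within ±1 (the systematic-resampling
guarantee); output weights are uniform `1/T_out`. Inputs must be ordered by
polar angle about the estimated center (the pipeline sorts internally; the
resampler itself rejects non-cyclically-monotone input). The predecessor of
the first point is the last point only when the data spans more than 300° of
polar angle; for shorter (open) arcs the first interval emits only its
original point, so its count may undershoot `T·W_1` — the proportionality
guarantee applies to intervals with a predecessor. Cumulative-sum float
drift is absorbed by a slack of 1e-9/T in the traversal comparison, far
below any interval width.

Interpolation is linear in the plane between consecutive points. When the
data has angular gaps, inserted points follow the chord across the gap; this
mirrors the method's sequential-neighbour definition and is harmless in
practice because weights, not geometry, decide how many points an interval
receives.

## Fitters

Five classical families behind one `fit(points, method)` contract, all
pre-normalizing the data (centroid shift, isotropic scale to RMS radius √2)
and de-normalizing the conic afterwards — this is standard conditioning
practice and makes every method equivariant under similarity transforms to
≈1e-10 or better:

- `algebraic`: conic least squares with the rotation-invariant quadratic
  normalization A² + B²/2 + C² = 1, solved as a reduced symmetric
  generalized eigenproblem. May return a hyperbola on noisy eccentric data;
  such fits are flagged `converged=False`, never silently projected.
- `direct`: ellipse-specific least squares under 4AC − B² = 1. The textbook
  selection rule ("the single positive generalized eigenvalue") degenerates
  on exact data where that eigenvalue is numerically ±0; we select by the
  equivalent ellipse condition on the eigenvector instead.
- `stable_direct`: the block decomposition of the same objective (3×3
  eigenproblem); agrees with `direct` to 1e-8 on well-conditioned data.
- `gradient_weighted`: algebraic residuals normalized by the mean squared
  conic gradient; smallest non-negative generalized eigenvalue, near-ties
  broken by algebraic residual.
- `sampson_mle`: Levenberg–Marquardt on the pointwise Sampson distances,
  initialized from `stable_direct`, convergence at relative cost change
  < 1e-12 or 200 iterations, plus a scale-invariant discriminant barrier
  ‖θ‖²/(4AC−B²) weighted at 1e-6 of the initial cost. The barrier is the
  decisive ingredient for partial arcs: without it the Sampson objective's
  infimum on two-cluster data is approached by ever larger, near-parabola
  ellipses. Non-ellipse or cost-increasing steps are rejected by raising
  the damping.

## Error evaluation

Orthogonal (geometric) distance to the ellipse is computed by reducing the
query point to the first quadrant of the ellipse frame and bisecting the
stationarity condition on `[0, π/2]`, where the nearest-point problem has
exactly one root (60 fixed iterations; since the objective is stationary at
the root, the distance error is second-order and far below 1e-10·a). This
is robust to the two-local-minima geometry of eccentric ellipses and
vectorizes over point sets. RMSE is the root mean square of these distances.

The benchmark harness records two RMSE variants per cell: the noisy data
against the fitted ellipse (the quantity a fitter approximately minimizes),
and the same sampled points at their noiseless positions against the fitted
ellipse (truth-referenced). The two disagree systematically on
sector-restricted data: a fit that collapses onto the noise clusters of a
narrow sector *lowers* its own-fit residual while being a much worse
ellipse. Trend statements about fit quality therefore use the
truth-referenced measure; the own-fit measure is reported alongside because
it is the natural residual on real data where no ground truth exists.

## Synthetic data

- Sector sampling draws parametric angles i.i.d. uniform over the union of
  the requested intervals and maps them through the parametric equation.
  Sector bounds are interpreted in *parametric* angle: this convention
  reproduces the reference sector ξ̄ values (a polar-angle reading gives
  ≈0.916 instead of 0.9368 for the narrowest sector), which we confirmed by
  quadrature before freezing.
- Noise is i.i.d. zero-mean Gaussian per coordinate with σ expressed as a
  fraction of the semi-major axis (normalized); an absolute mode exists.
  The reference ellipse for benchmarks is a=100, b=32 (ε = 0.947418) at the
  origin. The absolute scale is arbitrary — only ratios like σ and relative
  errors are meaningful — and RMSE magnitudes scale with it.
- Occluded arcs place n equally spaced parametric samples and delete the
  ⌊(1−visible_fraction)·n⌋ consecutive samples following the gap position,
  emulating a single tracking loss.
- The fourfold symmetrization (reflect about x, then y) produces point sets
  whose best fitting center is the origin by construction, the setting the
  closed-form theory assumes.

What the generator does *not* emulate: correlated (tracking) noise, outliers,
perspective distortion of the projected circle, or multiple simultaneous
occlusions. Passing benchmarks here demonstrate behaviour under clean
Gaussian perturbations of exact ellipse geometry, not under real imaging
artifacts.

## Supplementary-point theory

For an origin-centered axis-aligned truth `(a0, b0)` and first-quadrant
polar samples `(r_i, θ_i)` (reflections implied), the restricted
least-squares fit over the semi-axes alone has the closed form
`a1 = Σ r cos²θ / Σ cos²θ`, `b1 = Σ r sin²θ / Σ sin²θ` (verified against a
derivative-free minimizer to 1e-8). Note this radial-averaging fit is biased
low even on exact samples — `a1` is a weighted mean of radii, not `a0`.

Adding one supplementary point at `(R, α)` rescales the fit to
`(a1·β, b1·δ)` and changes the L2 approximation error by

    ΔΣ = π{(β−1)a1[2a0 − (β+1)a1] + (δ−1)b1[2b0 − (δ+1)b1]},

which matches the brute-force error difference to 1e-10 on random scenarios.
Each of the two terms is positive exactly when R lies strictly inside the
corresponding axis interval, e.g. `(min, max){a1, a1 + Δa_α}` with
`Δa_α = 2(a0 − a1)(Σcos²θ + cos²α)/cos²α` — this per-axis characterization
is exact and is what `off_axis_conditions` reports. Because ΔΣ is a *sum*
of the two terms, membership in a single interval does not by itself
guarantee improvement (the other term can dominate negatively); the
`branch` field therefore only reports the genuinely sufficient cases — both
intervals simultaneously, or the single relevant interval when α sits
exactly on an axis — and the exact ΔΣ accompanies every report. Boundary
ties (ΔΣ = 0) count as "no improvement".

Scenario classification (Types 1–4) aggregates the signs of the radial
residuals `r_i − r_ellipse(θ_i)` over the low-angle (θ < π/4) and high-angle
halves by majority vote, ties broken by the residual sum. For a Type 3
scenario on an ε = 0.99 ellipse, the ΔΣ > 0 radius range is wide for
near-axis supplementary points and collapses as α approaches π/2 — the
quantitative rationale for augmenting near the major-axis vertices.

## Benchmark harness

`run_sector_experiment` samples each sector (default: the five standard
nested sector pairs, 100 points per set, the narrowest hugging the
major-axis vertices), adds noise, optionally augments (axis source
configurable: true axes for synthetic studies, ensemble or two-pass
estimates otherwise), fits every method, and averages both RMSE measures
over repeats (default 250). Seeds are split per (σ, sector, repeat) with a
counter-based scheme, so runs are exactly reproducible and each cell is
statistically independent. A repeat enters a method's cell only if both
phases converged, keeping the raw/augmented comparison paired; failures are
counted per phase. `run_noise_sweep` aggregates across sectors and
normalizes each method's curve by its own maximum, so methods are compared
on relative degradation rather than absolute error.

Known limitations: the strict "error grows with sector eccentricity"
ordering holds cleanly for the direct least-squares family under the
truth-referenced measure, but not universally — the regularized Sampson
fitter is actually *most* accurate on the narrowest sectors, and the purely
algebraic fitters can dip slightly at the extreme sector — and the own-fit
measure inverts the ordering altogether on narrow sectors. The
augmentation improvement at σ = 0.2, by contrast, is robust across all five
families. Absolute RMSE values depend on the arbitrary ellipse scale and on
per-implementation conditioning choices and are not comparable across
codebases.
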