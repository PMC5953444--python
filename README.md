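# eccfit

Eccentricity-weighted data augmentation for robust ellipse fitting.

Least-squares ellipse fitters — algebraic and geometric alike — degrade when
the data concentrates far along the major axis of an eccentric ellipse. This
situation is the rule, not the exception, in applications such as plant root
phenotyping, where a tracked root tip imaged on a turntable traces a highly
eccentric ellipse that is often partially occluded near one of its ends.
`eccfit` implements a pre-processing step that measures how "eccentric" each
data point is, and strategically densifies the point set in those regions
before fitting, improving the fit of essentially any downstream method.

## The method

Given a rough estimate of the ellipse's center, axes and orientation, each
data point `X_s` receives an **eccentricity**

```
ξ_s = ε · d_a / (d_a + d_b),        ε = √(a² − b²) / a,
```

where `d_a` and `d_b` are the point's orthogonal distances to the minor- and
major-axis lines. `ξ_s ∈ [0, ε]` is largest for points near the major-axis
vertices — exactly where fits are weakest. Points are weighted

```
w_s = exp(ξ_s),     W_s = w_s / Σ_k w_k,
```

and a systematic resampling pass (a traversal of the cumulative weight
distribution with fixed step `1/T`, `T = ⌊1/min W_s⌋`) inserts points,
linearly interpolated between angular neighbours, in proportion to the local
weight. All original points are retained; the output is an augmented point
set ready for a second fitting pass.

The package also provides:

- **`geometry`** — parametric ↔ conic conversions, eccentricity from either
  representation, and exact orthogonal-distance / RMSE evaluation (nearest
  point on the ellipse).
- **`fitters`** — five classical fitting families behind one contract:
  plain algebraic least squares (quadratic normalization), direct
  ellipse-specific least squares, its numerically stable block variant,
  gradient-weighted algebraic fitting, and iterative Sampson-distance
  (approximate maximum-likelihood) minimization.
- **`synthdata`** — sector-restricted noisy samples, fourfold-symmetric
  point sets, and occluded arcs emulating tracked trajectories.
- **`theory`** — the closed-form answer to *when does adding a supplementary
  point at polar position (R, α) improve a restricted least-squares fit?*,
  including the improvement intervals for R and the scenario taxonomy.
- **`experiments`** — a deterministic Monte-Carlo harness benchmarking all
  fitters across sectors and noise levels, before and after augmentation.

## Worked example

`examples/augment_occluded_arc.py` fits a partially occluded eccentric
trajectory (58 of 72 turntable positions visible, ε = 0.95, 5% noise):

```
visible points: 58 of 72 (gap at a major vertex)
truth:     a= 100.00 b= 31.22
raw fit    a=  95.51 b= 32.86 |Δa|/a=0.045 |Δb|/b=0.052
augmented  a=  96.31 b= 32.02 |Δa|/a=0.037 |Δb|/b=0.025
(augmentation grew the point set from 58 to 110 points)
```

The direct fit on the raw arc underestimates the major axis by 4.5% and
misses the minor axis by 5.2%; after eccentricity-weighted augmentation the
same fitter halves the minor-axis error and reduces the major-axis error.
The other examples cover the five fitters side by side, the sector
benchmark (fit error grows with the data's mean point eccentricity ξ̄, and
augmentation recovers part of it), and the supplementary-point theory
(improvement intervals widest for near-axis additions).

A thin CLI mirrors the library: `eccfit fit`, `eccfit augment`,
`eccfit simulate`, `eccfit theory`, `eccfit bench {sector,sweep}`.

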