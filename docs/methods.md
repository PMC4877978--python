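# Methods

## Problem and conventions

Given counts observed only as interval totals over contiguous half-open
intervals `[e_i, e_{i+1})`, estimate the expected count `γ_j` (and the
density `γ_j / n`) per single-year bin on a unit grid covering the
grouped support. One convention is fixed throughout and matters for
exact round trips: intervals are half-open, ages are continuous within
bins, and single-year bins are labelled by their left edge. Open-ended
groups ("85+") must be closed explicitly by the user (typically at 115,
the age beyond which events are not expected); the reader refuses to
guess. A zero-count *closing interval* appended past the assumed maximum
age (e.g. `[115, 130)`) anchors the right tail: it tells the likelihood
and kernel methods that no mass lies there, and flattens the cumulative
curve for the interpolants.

## Spline interpolation of cumulative counts

The cumulative count function `F` is known exactly at interval edges.
Both variants build a piecewise cubic through these knots that is
non-decreasing whenever the data are, so unit differences
`f(x) = F(x+1) − F(x)` are non-negative:

- **pchip**: Fritsch–Carlson derivative limiting with the non-centered
  three-point endpoint formula (scipy's `PchipInterpolator`, which is
  also the algorithm behind the cited reference implementations).
- **hyman**: knot derivatives of a not-a-knot cubic spline, clamped into
  `[0, 3·min(Δ_{i−1}, Δ_i)]` (the sign-corrected Hyman clamp for
  non-decreasing data) and re-assembled as a Hermite cubic. The clamp is
  sufficient for per-segment monotonicity; second-derivative continuity
  is sacrificed where it binds.

Endpoint treatment is not canonical anywhere; the choices above are the
defaults of the respective reference implementations. Differencing can
produce round-off negatives of order 1e−12 at segment joins; these are
clipped to zero and the (sub-1e−9) deficit left unredistributed. Both
variants conserve each interval's count exactly (interpolation
property), a fact the tests assert to 1e−9. The pchip variant's "sudden
twist" just before a wide interval is part of the method under
comparison, not corrected.

## Penalized composite link model

`y_i ~ Poisson(μ_i)`, `μ = Cγ`, `γ = exp(β)`, with `C` the 0/1
composition matrix summing unit bins into observed intervals. The
penalized log-likelihood `L − (λ/2)‖D_k β‖²` is maximized by a modified
IRWLS: with `W = diag(μ)` and working design `X̆ = W⁻¹ C diag(γ)`,
solve `(X̆ᵀWX̆ + λD_kᵀD_k)β = X̆ᵀWz`, `z = X̆β + W⁻¹(y − μ)`.

Numerical choices:

- difference order k = 2 (null space: log-linear trends), the standard
  choice in the composite-link smoothing literature;
- λ selected by AIC = deviance + 2·ED over 50 log-spaced candidates in
  [1e−2, 1e7], swept smooth-to-rough with warm starts; a boundary
  minimum triggers a warning;
- ED = trace[(X̆ᵀWX̆ + λD₂ᵀD₂)⁻¹X̆ᵀWX̆];
- deviance `2Σ[y log(y/μ) − (y − μ)]` with `0·log 0 = 0`, so zero-count
  closing intervals contribute μ rather than NaN;
- β initialized at the log of the histogram-implied fine counts (uniform
  within intervals, floored at 1/J); steps clipped to ±10 in log space;
- convergence is declared on the relative change of the *penalized*
  objective (deviance + λ‖Dβ‖²), tolerance 1e−7, max 100 iterations:
  at very large λ the raw deviance stalls while β is still relaxing
  into the penalty null space, so monitoring deviance alone stops
  prematurely. The fitted optimum was cross-checked against an
  independent quasi-Newton minimization of the same objective
  (agreement to 1e−6 in the objective);
- Cholesky solves, with a 1e−10 ridge added only on factorization
  failure (wide-interval rows at tiny λ can make the system
  near-singular).

Total mass is conserved only approximately (relative error well under
1e−3): the penalty perturbs the score equations, so exact conservation
is deliberately not asserted. Note that "large λ" is relative to the
grid size: for J = 130 the smallest nonzero eigenvalue of `D₂ᵀD₂` is
~3e−9, so the penalty only dominates the likelihood from λ ≳ 1e10.

## Kernel estimators for binned data

Both use a Gaussian kernel and evaluate on the unit grid refined ×5
(0.2-year cells, trapezoid quadrature); the refinement increases to
dx ≈ h for bandwidths below 0.2, since trapezoid integration of a
Gaussian needs dx ≲ h. No boundary correction: mass smeared outside the
support is clipped and the density renormalized, negligible for
age-at-death shapes. Densities are converted to per-unit-bin masses by
integrating over each unit bin.

**ickde** iterates
`f_{t+1}(x) = Σ_i (c_i/n)·[∫_{bin i} K_h(x−u) f_t(u) du / ∫_{bin i} f_t(u) du]`
from the histogram density, renormalizing each step, until the sup-norm
change falls below 1e−6 (max 100 iterations). Within-bin masses are
floored at 1e−12 so zero-count stretches cannot divide by zero. The
histogram start is represented on the refined grid with the mean of
adjacent heights at interior edges, which keeps the trapezoid treatment
of the step's jump symmetric. The construction follows the published
sketch of the conditional-expectation idea; the cited implementation's
exact termination rule is not public, and bit-exact equivalence is not
claimed.

**bootkde** draws each observation uniformly within its interval,
forms a Gaussian KDE per replicate (B = 500), and averages. Because all
replicates share one bandwidth and the mean is renormalized once, the
implementation pools all B·n pseudo-draws into a single binned KDE —
algebraically identical to averaging per-replicate estimates, and
linear instead of quadratic in B. The bandwidth minimizes an estimated
integrated squared error `R(K)/(nh) + h⁴R(f″)/4` over a 30-point log
grid in [0.5, 30] years, with the curvature `R(f″)` estimated from the
binned mixture at a normal-scale pilot. Two candidate "held-out" ISE
proxies were rejected during design: scoring against held-out histogram
heights selects an h essentially independent of n (it only measures how
well neighbors bridge a missing bin), and a binned least-squares
cross-validation degenerates to the smallest candidate at large n
(substituting the within-bin conditional expectation for the held-out
observation removes the variance penalty). The estimated-MISE criterion
is a genuine ISE minimization with the correct n^(−1/5) behaviour. As
with ickde, this is this package's construction of the cited
bootstrap-type estimator, not a bit-exact reimplementation.

**Bandwidth selectors.** `plugin_bandwidth` is the two-stage direct
plug-in (normal-scale ψ₈ → ψ₆ → ψ₄ ladder, Gaussian kernel) computed on
pseudo-data that expands each count into equally spaced points within
its interval. `lcv_bandwidth` maximizes a leave-one-bin-out binned
likelihood `Σ_i c_i log ∫_{bin i} f̂_{−i,h}`. Holding out whole bins
pushes the likelihood toward bandwidths that bridge 5-year gaps, so LCV
systematically oversmooths relative to plug-in on grouped data — the
simulation harness therefore uses the plug-in selector for ickde, while
LCV remains available (and is the default in the CLI's empirical mode,
where plug-in tends to undersmooth noisy real tables).

## Distance measures

IAE `Σ|f̂−f|`, ISE `Σ(f̂−f)²`, KL `Σ f log(f/f̂)` as plain sums over
the single-year grid (Δx = 1, so no width weighting), densities
evaluated at bin left edges. For KL only, both densities are
renormalized to sum to one on the comparison grid and f̂ floored at
1e−12 (natural log); IAE and ISE compare the densities as-is. Under
these conventions KL ≥ 0 and Pinsker's inequality KL ≥ ½·IAE² holds,
which the tests exercise on random pairs.

## Simulation design and the synthetic-data generator

The target is Weibull(shape α = 8, scale β = 82): mode ≈ 80.6 years,
mean ≈ 77.2, a plausible adult age-at-death distribution; [0, 115)
carries 99.99997% of its mass, so inverse-CDF draws `β(−log U)^{1/α}`
at or above 115 are resampled, keeping n exact. Four scenarios cross
n ∈ {200, 1000} with two grouping schemes — A: 23 five-year classes
over 0–115; B: 17 five-year classes to 85 plus the wide `[85, 115)`
group — and both get the `[115, 130)` zero-count closing interval;
estimates are compared with the true density on the unit grid 0–130.
Per-replicate seeds derive from `(base_seed, replicate)` through a
counter-based seed sequence, so the data stream is identical whichever
methods are being compared (paired comparisons stay paired) and any run
is fully deterministic given its seed.

What the generator does *not* emulate: digit preference/age heaping,
abrupt multi-modal shapes, reporting errors, or the very small counts of
rare diseases. Passing the simulation suite therefore shows that the
methods recover a smooth unimodal density from coarse groupings — not
that they fit noisy empirical tables, where the smoothness assumption
itself is the main caveat.

Problem sizes in the shipped tests and acceptance script are 50
replications per scenario (the package's default comparison size;
the `Scenario` default of 500 reproduces the full study), 200 random
tables for the exact-conservation checks, and 10⁶ draws for the sampler
moment check.

## Known limitations

- Kernel methods require whole-year interval edges (quadrature cells are
  anchored to the unit grid).
- PCLM's identity basis (no B-splines) and one-dimensional penalty only.
- bootkde and ickde are constructions from the published descriptions of
  the cited estimators, validated by behaviour (oracle tests,
  qualitative ranking), not bitwise against the original software.
- The empirical-application workflow (reading registry-style 5-year
  tables, closing 85+ at 115) is supported but not validated against any
  bundled registry data.
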