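# Methods

## Model

The package implements a power-series predictor for a smooth scalar
function of time whose derivatives are observed at unsynchronized times.
Given the base value f(t₀) and one observation f⁽ⁿ⁾(tₙ) per derivative
order n = 1..N, the unsynchronized expansion is

    f(t₀+τ) = f(t₀) + Σₙ f⁽ⁿ⁾(tₙ) · Σₖ₌₁ⁿ τᵏ/k! · pₙₖ .

It is derived by recursively re-expanding each derivative about its own
observation time: f⁽ᵏ⁾(t₀) is written as the Taylor series of f⁽ᵏ⁾ about
tₖ, every resulting f⁽ᵐ⁾(tᵢ) with i ≠ m is re-expanded about tₘ, and terms
are collected per derivative order.  The coefficient pₙₖ that results is a
sum over *chains* k = i₀ < i₁ < … < iⱼ < i_{j+1} = n (the inner indices any
subset of {k+1, …, n−1}), each chain contributing

    Πₘ (t_{i_{m−1}} − t_{i_m})^(i_{m+1} − i_m) / (i_{m+1} − i_m)! ,

with the leading slot t_{i₋₁} ≡ t₀.  Two closed special cases follow
immediately: pₙₙ = 1 and p₍ₖ₊₁₎ₖ = t₀ − tₖ.  When all tₙ = t₀ every
difference factor vanishes and the expansion is the Taylor series.

On the uniform-lag schedule tₙ = t₀ − n·t each difference is an integer
multiple of t, so pₙₖ = cₙₖ·tⁿ⁻ᵏ with cₙₖ a pure rational (cₙₙ = 1,
c₍ₙ₎₍ₙ₋₁₎ = n−1, c₃₁ = 3/2, c₄₁ = 8/3, c₄₂ = 4, …).  This schedule — every
higher derivative one lag unit staler — is the most unfavorable regular
arrangement and is the reference configuration for all error studies here.

Assumptions: f is smooth enough for the truncated orders used; times are
dimensionless (normalized to an arbitrary time constant); derivative
values are measured, not estimated — no convergence or radius-of-validity
checking is performed, truncation error is the caller's concern and is
exposed by the error-analysis module.

## Coefficient computation and validation

* **Chain enumeration** (`p_coefficient`): depth-first generation of the
  strictly increasing inner index tuples; 2^(n−k−1) chains per
  coefficient.  Factorial divisors enter as exact `Fraction`s, so
  rational or symbolic schedules stay exact; float schedules collapse to
  float and chain contributions are combined with compensated summation
  (`math.fsum`).  Table construction is capped at order 12 by default and
  refuses larger requests with a capability error (the cap is an explicit
  argument for callers who accept the cost).
* **Exact rationals** (`c_coefficient`): same enumeration over integer
  index differences in `Fraction` arithmetic — no floating point.
* **Oracle 1, monomial matching** (built and verified first): requiring
  the truncated expansion to be exact on the monomials (t−t₀)^m forces
  the triangular recursion p_mm = 1,
  p_mk = −Σ_{n=k}^{m−1} (tₙ−t₀)^{m−n}/(m−n)! · p_nk.  This O(n²) route
  never enumerates chains and is the cheap independent check.
* **Oracle 2, symbolic re-expansion**: repeats the defining derivation
  mechanically in sympy (capped at order 6 for cost) and must agree both
  symbolically (low orders, against hand-collected terms) and numerically
  after substitution.

The three routes agree on random schedules up to order 6 at relative
1e−10 (observed: ~1e−15); the uniform-lag factorization pₙₖ = cₙₖ·tⁿ⁻ᵏ is
checked *exactly*, with the lag as a symbol, up to order 6.

## Predictors

`taylor_predict` sums the classical series; `u_predict` evaluates the
general expansion (inner sums Horner-style in τ, accumulation over
increasing order so per-order contributions remain inspectable in the
returned object); `u_predict_uniform` evaluates the uniform-lag form
through the exact rationals and requires the observation times to match
the t₀ − n·t pattern within 1e−12 absolute.  The two routes agree to
relative ~1e−15 on random draws.  Degenerate and repeated observation
times are allowed throughout.

## Error analysis

The signed truncation error is ε = f(t₀+τ) − prediction (exact minus
truncated; log-scale comparisons use |ε|).  Test functions are e^t about
t₀ = 0 and sin t about t₀ = π/4, with exact derivative evaluators; τ grids
are 60 log-spaced points on [1e−3, 1] for the wide view and 200 linear
points up to the range limit for the small-τ detail (the statements below
are grid-checkable at these densities).

Quantitative behavior established by the test suite:

* **Small-increment ladder**: for lag t = 0.01 and 0 < τ ≤ t, max |ε|
  falls below ≈1e−5, 1e−7, 1e−9 at truncation orders 2, 3, 4.  "About" is
  enforced as a strict bound at 2× with a warning in the 1×–2× band; the
  exponential order-4 value measures 1.05e−9, all others are below 1×.
* **Near-Taylor regime**: for t ≪ τ the relative departure of the
  unsynchronized error from the equal-order Taylor error follows the
  leading-order law ≈ nt(nt+1)·t/τ (the first neglected lag term over the
  first neglected Taylor term).  At t = 0.001, τ = 0.1 this is 6%–21%
  depending on order, shrinking like 1/τ; the suite asserts the law
  within a factor 2.  On a log-scale plot the curves are visually
  coincident, but a flat few-percent tolerance over all of τ ∈ [0.1, 1]
  is *not* attainable — the deviation at the τ = 0.1 end exceeds 5% for
  every order.
* **One-order gain**: for t ∈ {0.01, 0.05} the order-nt unsynchronized
  error stays below the order-(nt−1) Taylor error over τ ∈ [0.25, 1] for
  both test functions, and over [0.2, 1] for the exponential; the single
  exception is sin with t = 0.05, nt = 4 near τ = 0.2 (ratio 1.10,
  dropping below 1 by τ ≈ 0.22).
* **Drift toward lower orders**: at fixed τ = 0.05, |ε| is nondecreasing
  in t over {0.001, 0.01, 0.05, 0.1}; the order-3 curve at t = 0.05
  crosses the order-2 Taylor curve near τ ≈ 0.065 (at τ = 0.05 the two
  errors differ by a factor 1.40 — "equality" there is a log-plot
  reading, and the suite asserts the crossing plus factor-2 agreement).

## Backward finite-difference baseline

Without direct derivative sensing, the n-th derivative at t₀ is estimated
from the 2n most recent samples f(t₀), f(t₀−T), …, f(t₀−(2n−1)T) by an
n-th-order-accurate backward stencil whose weights solve the Vandermonde
moment conditions Σⱼ wⱼ(−j)^p = δ_{p,n}·n! (p = 0..2n−1), computed at run
time in exact rational arithmetic.  The resulting Taylor prediction
carries the acquisition lag (2n−1)·T and, at a matched lag scale
(T = t = 0.01, τ = 0.1), is less accurate than the unsynchronized
expansion (e.g. 6.7e−4 vs 2.9e−4 at order 2 for e^t).  No noise-robust
differentiation filtering is implemented.

## Synthetic sensor streams

`generate_stream` emulates a receptor array: per base time t₀ it emits
f(t₀) and the first N derivative values at uniform, jittered
(uniform ± width/2 around the uniform times, so max gap ≤ lag + width) or
explicit offsets, with additive i.i.d. Gaussian noise of std σ on every
observed value (the base value included).  All randomness flows through
one seeded numpy generator; σ = 0 streams are exact to 1e−12.  The noise
model is the minimal stand-in for receptor variability; the generator
does **not** model spike-train encoding, receptor adaptation, conduction
delays, or correlated/multiplicative noise, so passing tests bound
truncation and i.i.d.-noise behavior only, not performance on real
neural data.

`rolling_prediction` scores τ-ahead predictions along the stream.
Reference magnitudes (fixed seeds, recorded after the calibration run the
noise-band check is defined by): e^t, lag 0.01, nt = 4, τ = 0.1, 1000
steps — RMS 7.4e−7 noise-free; 1.0e−4 at σ = 1e−4 (noise on the base
value passes through with unit weight, so noise dominates and RMS ≈ σ).
Experiment sizes throughout the suite (50–1000 steps, orders ≤ 6) keep
the full run in seconds on one core.

## Design choices and limitations

* Derivative values are inputs in the predictor module by design;
  estimation lives only in the baseline.
* Errors are stored signed; magnitude is taken at comparison time.
* Argument errors (bad orders, malformed schedules, short records) and
  capability errors (order caps) are distinct exception types; the CLI
  maps them to exit codes 2 and 3. CSV numerics are written with 17
  significant digits; rationals as "num/den" strings.
* Scalar functions of one time variable only; no vector states, no
  complex time, no closed-loop control law — the package stops at
  prediction quality.
* No closed-form simplification of the chain sum is attempted beyond the
  diagonal and first-subdiagonal identities; coefficient growth
  asymptotics are out of scope.
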