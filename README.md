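# uexpand

Prediction of a time-varying quantity from derivative values observed at
**unsynchronized** times.

## The problem

The Taylor series predicts a smooth function ahead of a base time t₀,

```
f(t₀+τ) = f(t₀) + Σₖ f⁽ᵏ⁾(t₀) τᵏ/k!  ,
```

but it needs every derivative *at the same instant* t₀.  Sensor arrays —
the biological archetype is the body's receptor system, which reports a
physiological quantity and its first few time derivatives through separate
receptors and pathways — deliver each derivative at its own detection time
tₙ.  The **unsynchronized expansion** (U-expansion) generalizes the Taylor
series to exactly this situation:

```
f(t₀+τ) = f(t₀) + Σₙ f⁽ⁿ⁾(tₙ) · Σₖ₌₁ⁿ τᵏ/k! · pₙₖ
```

where the coefficients pₙₖ are sums of products of time differences along
chains of derivative orders (pₙₙ = 1, p₍ₖ₊₁₎ₖ = t₀ − tₖ, …).  When every
tₙ = t₀ the expansion collapses to the Taylor series.  For the uniform-lag
schedule tₙ = t₀ − n·t the lag power factors out, pₙₖ = cₙₖ·tⁿ⁻ᵏ, with
exact rational cₙₖ (c₃₁ = 3/2, c₄₁ = 8/3, c₄₂ = 4, …).

The package provides

- the coefficient algebra for arbitrary detection schedules (exact
  rationals on uniform-lag schedules), validated by two independent
  oracles: monomial matching and mechanical symbolic re-expansion;
- truncated predictors (Taylor, general, and uniform-lag routes);
- truncation-error analysis of the expansion against the Taylor series as
  a function of the lag t, the horizon τ, and the truncation order;
- the backward finite-difference baseline (estimate derivatives from 2n
  past samples, paying a (2n−1)·T acquisition lag, then Taylor-predict);
- a seeded generator of synthetic, optionally noisy, staggered sensor
  streams with rolling-horizon prediction experiments.

All times are dimensionless (normalized to an arbitrary time constant).

## Worked example

```python
import math
from uexpand import (UniformLagSchedule, exponential,
                     observations_from_function, u_predict)

# e^t observed with lag 0.05 per derivative order: f at t0=0, f' at -0.05,
# f'' at -0.10, f''' at -0.15
obs = observations_from_function(exponential(), UniformLagSchedule(0.0, 0.05, 3))
pred = u_predict(obs, tau=0.5, nt=3)
print(pred.value, math.exp(0.5) - pred.value)
```

prints (see `examples/02_unsynchronized_prediction.py` for the full script)

```
exact value f(t0+tau)           : 1.64872127
unsynchronized prediction        : 1.64164442  (error +7.08e-03)
Taylor with synchronized values  : 1.64583333  (error +2.89e-03)
```

Although every derivative was observed at a different, earlier time, the
third-order unsynchronized prediction of e^0.5 is within a factor ~2.5 of
the ideal synchronized Taylor error — and far below the second-order
Taylor error (2.4e-2) that an observer who discards the stale third
derivative would incur.

The other scripts in `examples/` demonstrate the coefficient tables, the
truncation-error sweeps, the finite-difference baseline trade-off, and the
noisy sensor-stream experiments, each printing the numbers it computes.

A thin CLI mirrors the library: `uexpand coeffs|predict|error-curves|simulate`
(see `uexpand --help`; exit codes 0/2/3 for success / argument error /
capability limit).

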