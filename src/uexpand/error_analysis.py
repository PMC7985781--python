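"""Truncation-error analysis and the sampled-record finite-difference baseline.

The central comparison: how does the truncation error of the unsynchronized
expansion, whose n-th derivative is observed a lag ``n*t`` in the past,
depart from the Taylor error as the lag ``t`` grows?  The signed error is

    eps = f(t0 + tau) - prediction

(exact value minus truncated series).  Errors are stored signed; the
log-scale comparisons all use ``|eps|``.

The baseline alternative to direct derivative sensing estimates every
derivative at ``t0`` by backward finite differences from a uniformly sampled
record of the function itself.  An n-th-order-accurate backward stencil for
the n-th derivative needs the ``2n`` most recent samples, so the estimate —
and hence the prediction — is only available once ``(2n-1)*T`` of record has
accumulated.  The stencil weights are generated at run time by solving the
moment conditions in exact rational arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .errors import ArgumentError
from .predictor import (
    DerivativeObservationSet,
    TruncatedPrediction,
    observations_from_function,
    taylor_predict,
    u_predict_uniform,
)
from .coefficients import UniformLagSchedule


# ---------------------------------------------------------------------------
# test functions

@dataclass(frozen=True)
class TestFunction:
    """A trajectory with exact derivatives of every order."""

    name: str
    value: Callable[[float], float]
    derivative: Callable[[int, float], float]  # (order n >= 1, time) -> value


def exponential() -> TestFunction:
    """``f(t) = e^t`` — every derivative is the function itself."""
    return TestFunction("exp", math.exp, lambda n, t: math.exp(t))


def sine() -> TestFunction:
    """``f(t) = sin(t)`` with the four-cycle of derivatives."""
    cycle = (math.sin, math.cos, lambda x: -math.sin(x), lambda x: -math.cos(x))
    return TestFunction("sin", math.sin, lambda n, t: cycle[n % 4](t))


def polynomial(coeffs: Sequence[float]) -> TestFunction:
    """Polynomial with ascending coefficients ``coeffs[i] * t^i``."""
    p = np.polynomial.Polynomial(list(coeffs))
    return TestFunction(
        f"poly{len(coeffs) - 1}",
        lambda t: float(p(t)),
        lambda n, t: float(p.deriv(n)(t)),
    )


def custom(name: str, value, derivative) -> TestFunction:
    return TestFunction(name, value, derivative)


BUILTIN_FUNCTIONS = {"exp": exponential, "sin": sine}


def get_function(name: str) -> TestFunction:
    """Look up a trajectory by name: ``exp``, ``sin``, or ``poly:c0,c1,...``."""
    if name.startswith("poly:"):
        try:
            return polynomial([float(x) for x in name[5:].split(",")])
        except ValueError:
            raise ArgumentError(f"malformed polynomial spec {name!r}") from None
    try:
        return BUILTIN_FUNCTIONS[name]()
    except KeyError:
        raise ArgumentError(
            f"unknown test function {name!r}; available: "
            f"{sorted(BUILTIN_FUNCTIONS)} or 'poly:c0,c1,...'"
        ) from None


# ---------------------------------------------------------------------------
# truncation error

#: tau grid used for the wide (log-scale) error overview
def wide_grid(n: int = 60) -> np.ndarray:
    return np.logspace(-3.0, 0.0, n)


#: tau grid used for the small-increment detail view, 0 < tau <= upper
def detail_grid(upper: float, n: int = 200) -> np.ndarray:
    return np.linspace(upper / n, upper, n)


def truncation_error(
    fn: TestFunction,
    t0: float,
    lag: float,
    tau: float,
    nt: int,
    scheme: str = "u",
) -> float:
    """Signed truncation error ``f(t0+tau) - prediction`` of one scheme.

    ``scheme="u"`` places the n-th derivative observation at ``t0 - n*lag``
    and evaluates the uniform-lag unsynchronized expansion; ``lag = 0`` (or
    ``scheme="taylor"``, which ignores ``lag``) evaluates the Taylor series —
    the two are the same code path in that case, so the degeneracy is exact.
    """
    if tau <= 0:
        raise ArgumentError(f"tau must be positive, got {tau}")
    if lag < 0:
        raise ArgumentError(f"lag must be nonnegative, got {lag}")
    if scheme not in ("u", "taylor"):
        raise ArgumentError(f"scheme must be 'u' or 'taylor', got {scheme!r}")
    if scheme == "taylor" or lag == 0:
        derivs = [fn.value(t0)] + [fn.derivative(n, t0) for n in range(1, nt + 1)]
        pred = taylor_predict(derivs, tau, nt)
    else:
        schedule = UniformLagSchedule(t0, lag, nt)
        obs = observations_from_function(fn, schedule)
        pred = u_predict_uniform(obs, tau, lag, nt)
    return fn.value(t0 + tau) - pred.value


@dataclass(frozen=True)
class TruncationErrorCurve:
    """Signed error over a tau grid for one function, lag, and order."""

    function_name: str
    t0: float
    lag: float  # 0 for the Taylor scheme
    nt: int
    scheme: str
    taus: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or len(taus) == 0 or np.any(np.diff(taus) <= 0):
            raise ArgumentError("tau grid must be a strictly increasing 1-d array")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "function": self.function_name,
                "t0": self.t0,
                "t": self.lag,
                "nt": self.nt,
                "scheme": self.scheme,
                "tau": self.taus,
                "error": self.errors,
            }
        )


def error_curve(
    fn: TestFunction,
    t0: float,
    lag: float,
    nt: int,
    tau_grid: Sequence[float],
    scheme: str = "u",
) -> TruncationErrorCurve:
    """Vectorize :func:`truncation_error` over a tau grid."""
    taus = np.asarray(tau_grid, dtype=float)
    errs = np.array([truncation_error(fn, t0, lag, tau, nt, scheme) for tau in taus])
    return TruncationErrorCurve(fn.name, t0, lag, nt, scheme, taus, errs)


def max_abs_error(curve: TruncationErrorCurve, tau_range: tuple) -> float:
    """Largest ``|error|`` over the grid points inside ``tau_range`` (inclusive)."""
    lo, hi = tau_range
    mask = (curve.taus >= lo) & (curve.taus <= hi)
    if not mask.any():
        raise ArgumentError(
            f"tau range {tau_range} contains no grid point of the curve "
            f"(grid spans [{curve.taus[0]}, {curve.taus[-1]}])"
        )
    return float(np.max(np.abs(curve.errors[mask])))


# ---------------------------------------------------------------------------
# backward finite-difference baseline

@dataclass(frozen=True)
class SampledRecord:
    """Uniformly sampled history of ``f``: ``values[j] = f(t0 - j*T)``."""

    t0: float
    period: float
    values: tuple

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ArgumentError(f"sampling period must be positive, got {self.period}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


def sample_record(fn: TestFunction, t0: float, period: float, count: int) -> SampledRecord:
    """Record the last ``count`` samples of ``fn`` ending at ``t0``."""
    return SampledRecord(
        t0, period, tuple(fn.value(t0 - j * period) for j in range(count))
    )


def backward_fd_weights(n: int) -> tuple:
    """Exact stencil weights for the n-th derivative on ``2n`` backward samples.

    Solves the moment conditions ``sum_j w_j (-j)^p = delta_{p,n} * n!`` for
    ``p = 0 .. 2n-1`` by Gaussian elimination over ``Fraction``; the estimate
    is then ``f^(n)(t0) ~= T^-n sum_j w_j f(t0 - j*T)``, exact for
    polynomials up to degree ``2n-1`` and hence n-th-order accurate.
    """
    if n < 1:
        raise ArgumentError(f"derivative order must be >= 1, got {n}")
    m = 2 * n
    a = [[Fraction((-j) ** p) for j in range(m)] for p in range(m)]
    b = [Fraction(math.factorial(n)) if p == n else Fraction(0) for p in range(m)]
    for col in range(m):  # exact elimination; Vandermonde system is nonsingular
        piv = next(r for r in range(col, m) if a[r][col] != 0)
        a[col], a[piv] = a[piv], a[col]
        b[col], b[piv] = b[piv], b[col]
        inv = 1 / a[col][col]
        a[col] = [x * inv for x in a[col]]
        b[col] *= inv
        for r in range(m):
            if r != col and a[r][col] != 0:
                f = a[r][col]
                a[r] = [x - f * y for x, y in zip(a[r], a[col])]
                b[r] -= f * b[col]
    return tuple(b)


def backward_fd_derivatives(record: SampledRecord, n: int) -> float:
    """n-th derivative at ``t0`` from the ``2n`` most recent samples."""
    w = backward_fd_weights(n)
    if len(record.values) < 2 * n:
        raise ArgumentError(
            f"order-{n} backward difference needs 2n = {2 * n} samples, "
            f"record holds {len(record.values)}"
        )
    acc = math.fsum(float(wj) * v for wj, v in zip(w, record.values))
    return acc / record.period**n


@dataclass(frozen=True)
class BackwardFDPrediction(TruncatedPrediction):
    """Taylor prediction from finite-difference derivative estimates.

    Carries the acquisition cost of the §-free alternative: ``samples_used``
    function samples and an ``acquisition_lag`` of ``(2*nt - 1) * T`` before
    the highest-order stencil is complete.
    """

    samples_used: int = 0
    acquisition_lag: float = 0.0


def backward_fd_predict(record: SampledRecord, tau: float, nt: int) -> BackwardFDPrediction:
    """Predict ``f(t0 + tau)`` with derivatives estimated from the record."""
    if nt < 1:
        raise ArgumentError(f"truncation order must be >= 1, got {nt}")
    if len(record.values) < 2 * nt:
        raise ArgumentError(
            f"order-{nt} prediction needs 2*nt = {2 * nt} samples, "
            f"record holds {len(record.values)}"
        )
    derivs = [record.values[0]] + [backward_fd_derivatives(record, n) for n in range(1, nt + 1)]
    pred = taylor_predict(derivs, tau, nt)
    return BackwardFDPrediction(
        value=pred.value,
        nt=nt,
        tau=tau,
        scheme="backward-fd",
        contributions=pred.contributions,
        samples_used=2 * nt,
        acquisition_lag=(2 * nt - 1) * record.period,
    )


# ---------------------------------------------------------------------------
# plotting

def plot_error_curves(curves: Sequence[TruncationErrorCurve], path=None, ax=None):
    """Log-scale overlay of ``|error|`` vs tau for a set of curves."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        style = "--" if c.scheme == "taylor" else "-"
        label = f"{c.function_name} {'Taylor' if c.scheme == 'taylor' else f'U t={c.lag:g}'} nt={c.nt}"
        ax.plot(c.taus, np.abs(c.errors), style, label=label)
    ax.set_xlabel(r"$\tau$")
    ax.set_ylabel("|error|")
    ax.set_yscale("log")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
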