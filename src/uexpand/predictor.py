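"""Truncated series predictors: Taylor and the unsynchronized expansion.

Derivative values are *supplied*, never estimated here — the premise is a
sensor array that measures the quantity and its time derivatives directly,
each at its own time.  Finite-difference estimation from a sampled record
lives in :mod:`uexpand.error_analysis` as the comparison baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .coefficients import (
    ORDER_CAP,
    DetectionSchedule,
    UniformLagSchedule,
    c_coefficient,
    coefficient_table,
)
from .errors import ArgumentError

#: Absolute tolerance for recognizing a uniform-lag observation pattern.
UNIFORM_LAG_ATOL = 1e-12


@dataclass(frozen=True)
class DerivativeObservationSet:
    """``f(t0)`` plus one observed derivative value per order ``1..N``.

    ``observations`` holds ``(order, time, value)`` triples with contiguous
    orders starting at 1; the expansion consumes every order up to the
    truncation order, so gaps are rejected.  Times need not be ordered or
    distinct.
    """

    t0: float
    f0: float
    observations: tuple  # of (n, t_n, value) triples

    def __post_init__(self) -> None:
        obs = tuple(tuple(o) for o in self.observations)
        object.__setattr__(self, "observations", obs)
        orders = [o[0] for o in obs]
        if orders != list(range(1, len(obs) + 1)):
            raise ArgumentError(
                f"observations must carry contiguous orders 1..N, got orders {orders}"
            )

    @property
    def N(self) -> int:
        return len(self.observations)

    @property
    def schedule(self) -> DetectionSchedule:
        return DetectionSchedule(self.t0, tuple(o[1] for o in self.observations))

    def value(self, n: int) -> float:
        """Observed value of the n-th derivative."""
        if not 1 <= n <= self.N:
            raise ArgumentError(f"no observation of order {n} (have 1..{self.N})")
        return self.observations[n - 1][2]


@dataclass(frozen=True)
class TruncatedPrediction:
    """Result of one truncated-series evaluation."""

    value: float
    nt: int
    tau: float
    scheme: str  # "taylor" | "u" | "backward-fd"
    #: per-order contributions f^(n)(t_n) * inner_sum_n (diagnostic)
    contributions: tuple = field(default=(), repr=False)


def taylor_predict(
    derivatives_at_t0: Sequence[float], tau: float, nt: int
) -> TruncatedPrediction:
    """Taylor prediction ``f(t0) + sum_{k<=nt} f^(k)(t0) tau^k / k!``.

    ``derivatives_at_t0[k]`` is the k-th derivative at ``t0`` (index 0 the
    function value), so the list must hold ``nt + 1`` entries.
    """
    if nt < 1:
        raise ArgumentError(f"truncation order must be >= 1, got {nt}")
    if len(derivatives_at_t0) < nt + 1:
        raise ArgumentError(
            f"need {nt + 1} values f(t0), f'(t0), ..., f^({nt})(t0); "
            f"got {len(derivatives_at_t0)}"
        )
    contribs = [
        derivatives_at_t0[k] * tau**k / math.factorial(k) for k in range(1, nt + 1)
    ]
    value = derivatives_at_t0[0] + math.fsum(contribs)
    return TruncatedPrediction(value, nt, tau, "taylor", tuple(contribs))


def _inner_sum(tau: float, coeffs_k: Sequence[float]) -> float:
    """``sum_k tau^k / k! * coeff_k`` for ``k = 1..n``, Horner-style in tau."""
    acc = 0.0
    for k in range(len(coeffs_k), 0, -1):
        acc = acc * tau + coeffs_k[k - 1] / math.factorial(k)
    return acc * tau


def u_predict(obs: DerivativeObservationSet, tau: float, nt: int) -> TruncatedPrediction:
    """Unsynchronized prediction from derivative values observed at their own times.

    Evaluates ``f(t0) + sum_{n<=nt} f^(n)(t_n) * sum_{k<=n} tau^k/k! p_nk``
    with the coefficients of the schedule embedded in ``obs``.  Accumulation
    runs over increasing order ``n`` so per-order contributions remain
    inspectable in the returned prediction.
    """
    if nt < 1:
        raise ArgumentError(f"truncation order must be >= 1, got {nt}")
    if nt > obs.N:
        raise ArgumentError(f"truncation order nt={nt} exceeds observation count N={obs.N}")
    table = coefficient_table(obs.schedule, nt)  # raises CapabilityError past cap
    contribs = []
    for n in range(1, nt + 1):
        inner = _inner_sum(tau, [table.p(n, k) for k in range(1, n + 1)])
        contribs.append(obs.value(n) * inner)
    value = obs.f0 + math.fsum(contribs)
    return TruncatedPrediction(value, nt, tau, "u", tuple(contribs))


def u_predict_uniform(
    obs: DerivativeObservationSet, tau: float, lag: float, nt: int
) -> TruncatedPrediction:
    """Uniform-lag unsynchronized prediction via the exact rational coefficients.

    Requires the observation times to follow ``t_n = t0 - n*lag`` (within
    ``UNIFORM_LAG_ATOL``); evaluates the inner sums as
    ``sum_k tau^k/k! c_nk lag^(n-k)``.
    """
    if nt < 1:
        raise ArgumentError(f"truncation order must be >= 1, got {nt}")
    if nt > obs.N:
        raise ArgumentError(f"truncation order nt={nt} exceeds observation count N={obs.N}")
    for n, tn, _ in obs.observations:
        expected = obs.t0 - n * lag
        if abs(tn - expected) > UNIFORM_LAG_ATOL:
            raise ArgumentError(
                f"observation time t_{n}={tn!r} deviates from the uniform-lag "
                f"pattern t0 - n*lag = {expected!r} by more than {UNIFORM_LAG_ATOL}"
            )
    contribs = []
    for n in range(1, nt + 1):
        coeffs = [
            float(c_coefficient(n, k)) * lag ** (n - k) for k in range(1, n + 1)
        ]
        contribs.append(obs.value(n) * _inner_sum(tau, coeffs))
    value = obs.f0 + math.fsum(contribs)
    return TruncatedPrediction(value, nt, tau, "u", tuple(contribs))


def observations_from_function(
    fn, schedule: DetectionSchedule
) -> DerivativeObservationSet:
    """Exact observation set for a test function on a detection schedule.

    ``fn`` follows the :class:`~uexpand.error_analysis.TestFunction`
    protocol (``fn.value(t)`` and ``fn.derivative(n, t)``).
    """
    obs = tuple(
        (n, schedule.time(n), fn.derivative(n, schedule.time(n)))
        for n in range(1, schedule.N + 1)
    )
    return DerivativeObservationSet(schedule.t0, fn.value(schedule.t0), obs)
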