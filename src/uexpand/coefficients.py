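"""Coefficient algebra of the unsynchronized power-series expansion.

The unsynchronized expansion (U-expansion) predicts ``f(t0 + tau)`` from the
base value ``f(t0)`` and derivative values ``f^(n)(t_n)`` observed at
arbitrarily different times ``t_n``:

    f(t0 + tau) = f(t0) + sum_n  f^(n)(t_n) * sum_{k=1}^{n} tau^k/k! * p_nk

The coefficient ``p_nk`` attached to ``f^(n)(t_n) * tau^k/k!`` is a sum of
products of time differences along "chains" of derivative orders.  With the
chain written as ``k = i_0 < i_1 < ... < i_j < i_{j+1} = n`` (the inner
indices ranging over any subset of ``{k+1, ..., n-1}``, including the empty
one) each chain contributes

    prod_{m=0}^{j}  (t_{i_{m-1}} - t_{i_m})^(i_{m+1} - i_m) / (i_{m+1} - i_m)!

where the leading slot ``t_{i_{-1}}`` is the base time ``t0``.  Special
cases: ``p_nn = 1`` and ``p_{k+1,k} = t0 - t_k``.

For the uniform-lag schedule ``t_n = t0 - n*t`` every time difference becomes
an integer multiple of the lag ``t``, the lag power ``t^(n-k)`` factors out,
and the residual coefficient ``c_nk = p_nk / t^(n-k)`` is an exact rational
(``c_nn = 1``, ``c_{n,n-1} = n-1``, ``c_31 = 3/2``, ``c_41 = 8/3``, ...).

Two independent oracles validate the chain enumeration:

* :func:`oracle_coefficients_monomial` determines the coefficients by
  requiring the truncated expansion to be exact on monomials
  ``(t - t0)^m`` — a triangular recursion that never enumerates chains.
* :func:`oracle_coefficients_reexpansion` mechanically repeats the recursive
  Taylor re-expansion that defines the series, in exact symbolic arithmetic.

The number of chains for one coefficient is ``2^(n-k-1)``, so table
construction is capped (default order 12) and refuses larger requests with a
:class:`~uexpand.errors.CapabilityError`.
"""

from __future__ import annotations

import math
import numbers
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Any

from .errors import ArgumentError, CapabilityError

#: Largest derivative order for which coefficient tables are built by
#: default.  Chain count doubles per order; 12 keeps the worst single
#: coefficient at 2**10 = 1024 chains.
ORDER_CAP = 12


def _is_number(x: Any) -> bool:
    return isinstance(x, numbers.Real) and not isinstance(x, bool)


@dataclass(frozen=True)
class DetectionSchedule:
    """Base time ``t0`` plus the observation times ``t_1 .. t_N``.

    ``times[n-1]`` is the time at which the n-th derivative is observed.
    Times may repeat and need not be ordered; entries may also be exact
    rationals or symbolic expressions (used by the validation oracles).
    """

    t0: Any
    times: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(self.times))
        if len(self.times) == 0:
            raise ArgumentError("a detection schedule needs at least one observation time")
        for x in (self.t0, *self.times):
            if _is_number(x) and not math.isfinite(float(x)):
                raise ArgumentError(f"schedule times must be finite, got {x!r}")

    @property
    def N(self) -> int:
        """Number of derivative orders covered by the schedule."""
        return len(self.times)

    def time(self, n: int):
        """Observation time of the n-th derivative; ``n = 0`` returns ``t0``."""
        if n == 0:
            return self.t0
        if not 1 <= n <= self.N:
            raise ArgumentError(f"derivative order {n} outside schedule range 1..{self.N}")
        return self.times[n - 1]

    @property
    def max_gap(self):
        """Maximum spacing ``max_i |t_i - t_{i-1}|`` with ``t_0`` included.

        This is the lag scale that controls how far the truncation error of
        the unsynchronized expansion departs from the Taylor error.
        """
        seq = (self.t0, *self.times)
        return max(abs(b - a) for a, b in zip(seq, seq[1:]))


class UniformLagSchedule(DetectionSchedule):
    """Schedule with the n-th derivative observed at ``t_n = t0 - n*lag``.

    The most unfavorable regular arrangement: higher-order derivatives are
    progressively staler.  ``max_gap`` equals the lag exactly.
    """

    def __init__(self, t0: Any, lag: Any, N: int):
        if _is_number(lag) and not lag > 0:
            raise ArgumentError(f"lag must be positive, got {lag!r}")
        if N < 1:
            raise ArgumentError(f"N must be a positive integer, got {N!r}")
        object.__setattr__(self, "lag", lag)
        super().__init__(t0, tuple(t0 - n * lag for n in range(1, N + 1)))

    @property
    def max_gap(self):
        return self.lag


def _chain_term(times_prev, chain):
    """Product of difference factors along one index chain.

    ``chain`` is ``(i_0, i_1, ..., i_{j+1})`` and ``times_prev[m]`` /
    ``times_prev[m+1]`` supply ``t_{i_{m-1}}`` and ``t_{i_m}``.  The
    factorial divisors enter as exact rationals so that Fraction-valued or
    symbolic schedules stay exact; float schedules collapse to float.
    """
    term = 1
    for m in range(len(chain) - 1):
        e = chain[m + 1] - chain[m]
        base = times_prev[m] - times_prev[m + 1]
        term = term * base**e * Fraction(1, math.factorial(e))
    return term


def p_coefficient(schedule: DetectionSchedule, n: int, k: int):
    """Coefficient of ``f^(n)(t_n) * tau^k / k!`` in the unsynchronized expansion.

    Evaluates the chain sum by depth-first enumeration of the strictly
    increasing inner index tuples between ``k`` and ``n`` (``2^(n-k-1)``
    chains).  Contributions are combined with compensated summation when the
    schedule is numeric.
    """
    if not 1 <= k <= n:
        raise ArgumentError(f"orders must satisfy 1 <= k <= n, got n={n}, k={k}")
    if n > schedule.N:
        raise ArgumentError(f"order n={n} exceeds schedule length N={schedule.N}")
    if n == k:
        return 1.0 if _is_number(schedule.t0) else 1
    inner = range(k + 1, n)
    terms = []
    for j in range(0, n - k):
        for subset in combinations(inner, j):
            chain = (k, *subset, n)
            # leading slot is t0, then the chain's own times (last omitted:
            # t_{i_{j+1}} = t_n never appears as a minuend or subtrahend-prev)
            times_prev = (schedule.t0, *(schedule.time(i) for i in chain[:-1]))
            terms.append(_chain_term(times_prev, chain))
    if all(isinstance(t, float) for t in terms):
        return math.fsum(terms)
    return sum(terms)


def c_coefficient(n: int, k: int) -> Fraction:
    """Exact rational coefficient ``c_nk`` of the uniform-lag expansion.

    On the schedule ``t_n = t0 - n*t`` every chain factor
    ``t_{i_{m-1}} - t_{i_m}`` equals ``(i_m - i_{m-1}) * t`` (with the base
    slot acting as index 0), so the lag power ``t^(n-k)`` factors out of
    ``p_nk`` and the remainder is the pure rational computed here.
    """
    if not 1 <= k <= n:
        raise ArgumentError(f"orders must satisfy 1 <= k <= n, got n={n}, k={k}")
    if n == k:
        return Fraction(1)
    total = Fraction(0)
    for j in range(0, n - k):
        for subset in combinations(range(k + 1, n), j):
            chain = (k, *subset, n)
            term = Fraction(1)
            prev_idx = 0  # base slot: t0 - t_k = k * t
            for m in range(len(chain) - 1):
                e = chain[m + 1] - chain[m]
                term *= Fraction((chain[m] - prev_idx) ** e, math.factorial(e))
                prev_idx = chain[m]
            total += term
    return total


@dataclass
class CoefficientTable:
    """Triangular table of expansion coefficients ``p_nk``, ``1 <= k <= n <= n_max``.

    For uniform-lag schedules the exact rationals ``c_nk`` are kept alongside
    (``p_nk = c_nk * lag^(n-k)``).
    """

    schedule: DetectionSchedule
    n_max: int
    entries: dict = field(repr=False)
    rational_entries: dict | None = field(default=None, repr=False)

    def p(self, n: int, k: int):
        if not 1 <= k <= n <= self.n_max:
            raise ArgumentError(f"(n={n}, k={k}) outside table range n_max={self.n_max}")
        return self.entries[(n, k)]

    def c(self, n: int, k: int) -> Fraction:
        if self.rational_entries is None:
            raise ArgumentError("rational coefficients only exist for uniform-lag tables")
        if not 1 <= k <= n <= self.n_max:
            raise ArgumentError(f"(n={n}, k={k}) outside table range n_max={self.n_max}")
        return self.rational_entries[(n, k)]

    def items(self):
        for n in range(1, self.n_max + 1):
            for k in range(1, n + 1):
                yield (n, k), self.entries[(n, k)]

    def substitute(self, schedule: DetectionSchedule) -> "CoefficientTable":
        """Evaluate a symbolic table on a numeric schedule (oracle output)."""
        import sympy

        sym = self.schedule
        subs = {sym.t0: schedule.t0}
        for i in range(1, min(sym.N, schedule.N) + 1):
            subs[sym.time(i)] = schedule.time(i)
        entries = {
            nk: float(sympy.sympify(v).subs(subs)) for nk, v in self.entries.items()
        }
        return CoefficientTable(schedule=schedule, n_max=self.n_max, entries=entries)


def _check_cap(n_max: int, cap: int) -> None:
    if n_max < 1:
        raise ArgumentError(f"n_max must be positive, got {n_max}")
    if n_max > cap:
        raise CapabilityError(
            f"n_max={n_max} exceeds the coefficient order cap {cap}: the chain "
            f"count grows as 2^(n-k-1); raise the cap explicitly if you accept the cost"
        )


def coefficient_table(
    schedule: DetectionSchedule, n_max: int, cap: int = ORDER_CAP
) -> CoefficientTable:
    """Build the full coefficient table up to order ``n_max``.

    Uniform-lag schedules are evaluated through the exact rationals
    ``c_nk``; general schedules through the chain enumeration.
    """
    _check_cap(n_max, cap)
    if n_max > schedule.N:
        raise ArgumentError(f"n_max={n_max} exceeds schedule length N={schedule.N}")
    if isinstance(schedule, UniformLagSchedule):
        rational = {
            (n, k): c_coefficient(n, k)
            for n in range(1, n_max + 1)
            for k in range(1, n + 1)
        }
        entries = {
            (n, k): float(c) * schedule.lag ** (n - k) for (n, k), c in rational.items()
        }
        return CoefficientTable(schedule, n_max, entries, rational_entries=rational)
    entries = {
        (n, k): p_coefficient(schedule, n, k)
        for n in range(1, n_max + 1)
        for k in range(1, n + 1)
    }
    return CoefficientTable(schedule, n_max, entries)


def oracle_coefficients_monomial(
    schedule: DetectionSchedule, n_max: int, cap: int = ORDER_CAP
) -> CoefficientTable:
    """Coefficients forced by exactness on the monomials ``(t - t0)^m``.

    Requiring the expansion truncated at order ``m`` to reproduce
    ``(t0 + tau - t0)^m = tau^m`` for every ``tau`` and matching powers of
    ``tau`` yields the triangular recursion

        p_mm = 1,
        p_mk = - sum_{n=k}^{m-1} (t_n - t0)^(m-n)/(m-n)! * p_nk    (k < m),

    which never touches the chain enumeration and therefore serves as an
    independent oracle for it.
    """
    _check_cap(n_max, cap)
    if n_max > schedule.N:
        raise ArgumentError(f"n_max={n_max} exceeds schedule length N={schedule.N}")
    p: dict = {}
    for m in range(1, n_max + 1):
        # diagonal of the triangular system is f^(m) of the monomial = m! != 0
        p[(m, m)] = 1.0 if _is_number(schedule.t0) else 1
        for k in range(m - 1, 0, -1):
            acc = []
            for n in range(k, m):
                d = schedule.time(n) - schedule.t0
                acc.append(d ** (m - n) / math.factorial(m - n) * p[(n, k)])
            p[(m, k)] = -math.fsum(acc) if all(isinstance(a, float) for a in acc) else -sum(acc)
    return CoefficientTable(schedule, n_max, p)


def oracle_coefficients_reexpansion(n_max: int) -> CoefficientTable:
    """Symbolic coefficients obtained by recursive Taylor re-expansion.

    Reproduces the derivation of the series mechanically: each derivative
    ``f^(k)(t0)`` is written as the Taylor series of ``f^(k)`` about ``t_k``,
    and every resulting ``f^(m)(t_i)`` with ``i != m`` is recursively
    re-expanded about ``t_m``, truncating above ``n_max``.  Collecting the
    terms per derivative order yields ``p_nk`` as polynomials in the
    symbolic times ``t0 .. t_{n_max}``.

    Because every re-expansion step strictly increases the derivative order,
    truncation at ``n_max`` is exact for all collected orders ``n <= n_max``.
    """
    import sympy

    if n_max < 1:
        raise ArgumentError(f"n_max must be positive, got {n_max}")
    if n_max > 6:
        raise CapabilityError(
            f"symbolic re-expansion is capped at order 6 (requested {n_max})"
        )
    ts = sympy.symbols(f"t0:{n_max + 1}")
    memo: dict = {}

    def expand(q: int, i: int) -> dict:
        """f^(q) evaluated at time index i, as {order n: coeff of f^(n)(t_n)}."""
        if i == q:
            return {q: sympy.Integer(1)}
        if (q, i) in memo:
            return memo[(q, i)]
        out: dict = defaultdict(lambda: sympy.Integer(0))
        out[q] += 1  # zeroth re-expansion term: f^(q)(t_q) itself
        for r in range(1, n_max - q + 1):
            coeff = (ts[i] - ts[q]) ** r / math.factorial(r)
            for order, c in expand(q + r, q).items():
                out[order] += coeff * c
        memo[(q, i)] = dict(out)
        return memo[(q, i)]

    entries = {}
    for k in range(1, n_max + 1):
        collected = expand(k, 0)
        for n in range(k, n_max + 1):
            entries[(n, k)] = sympy.expand(collected.get(n, sympy.Integer(0)))
    sym_schedule = DetectionSchedule(ts[0], ts[1:])
    return CoefficientTable(sym_schedule, n_max, entries)
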