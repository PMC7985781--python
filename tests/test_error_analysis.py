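"""Truncation-error behavior vs the Taylor reference, and the FD baseline."""

import math

import numpy as np
import pytest

from uexpand import (
    ArgumentError,
    SampledRecord,
    backward_fd_derivatives,
    backward_fd_predict,
    backward_fd_weights,
    detail_grid,
    error_curve,
    exponential,
    get_function,
    max_abs_error,
    polynomial,
    sample_record,
    sine,
    truncation_error,
    wide_grid,
)

EXP = exponential()
SIN = sine()
CASES = [(EXP, 0.0), (SIN, math.pi / 4)]


class TestTestFunctions:
    @pytest.mark.parametrize(
        "fn", [EXP, SIN, polynomial([1.0, -2.0, 0.5, 0.25])], ids=lambda f: f.name
    )
    def test_derivatives_agree_with_central_differences(self, fn):
        h = 1e-5
        for t in (-0.3, 0.0, 0.7):
            d1 = (fn.value(t + h) - fn.value(t - h)) / (2 * h)
            d2 = (fn.value(t + h) - 2 * fn.value(t) + fn.value(t - h)) / h**2
            assert fn.derivative(1, t) == pytest.approx(d1, abs=1e-6)
            assert fn.derivative(2, t) == pytest.approx(d2, abs=1e-4)

    def test_lookup_by_name(self):
        assert get_function("exp").name == "exp"
        assert get_function("poly:1,0,2").value(3.0) == pytest.approx(19.0)
        with pytest.raises(ArgumentError, match="unknown test function"):
            get_function("tan")


class TestTruncationError:
    def test_taylor_error_closed_form(self):
        eps = truncation_error(EXP, 0.0, 0.0, 0.1, 1, "taylor")
        assert eps == pytest.approx(math.exp(0.1) - 1.1, rel=1e-12)

    def test_zero_lag_is_exactly_the_taylor_error(self):
        """lag = 0 follows the identical code path as the Taylor scheme."""
        for fn, t0 in CASES:
            for nt in (1, 2, 3, 4):
                for tau in (0.05, 0.3, 1.0):
                    assert truncation_error(fn, t0, 0.0, tau, nt, "u") == \
                        truncation_error(fn, t0, 0.0, tau, nt, "taylor")

    def test_polynomial_error_identically_zero(self):
        fn = polynomial([1.0, 2.0, -0.5])
        curve = error_curve(fn, 0.2, 0.05, 2, detail_grid(0.3))
        assert max_abs_error(curve, (0.0, 0.3)) < 1e-12

    def test_invalid_arguments(self):
        with pytest.raises(ArgumentError):
            truncation_error(EXP, 0.0, 0.01, -0.1, 2)
        with pytest.raises(ArgumentError):
            truncation_error(EXP, 0.0, -0.01, 0.1, 2)
        with pytest.raises(ArgumentError):
            truncation_error(EXP, 0.0, 0.01, 0.1, 2, scheme="pade")

    def test_max_abs_error_range_handling(self):
        curve = error_curve(EXP, 0.0, 0.01, 2, wide_grid())
        with pytest.raises(ArgumentError, match="no grid point"):
            max_abs_error(curve, (2.0, 3.0))


class TestLagRegimes:
    """Quantitative behavior of the unsynchronized error vs the lag."""

    @pytest.mark.parametrize("fn,t0", CASES, ids=["exp", "sin"])
    @pytest.mark.parametrize("nt", [2, 3, 4])
    def test_near_taylor_deviation_follows_leading_order_law(self, fn, t0, nt):
        """For lag << tau the relative departure from the Taylor error is
        ~ nt(nt+1)*lag/tau to leading order; assert within a factor 2 of it."""
        lag = 0.001
        for tau in np.logspace(np.log10(0.1), 0.0, 13):
            eu = truncation_error(fn, t0, lag, tau, nt, "u")
            et = truncation_error(fn, t0, 0.0, tau, nt, "taylor")
            dev = abs(eu - et) / abs(et)
            assert dev <= 2.0 * nt * (nt + 1) * lag / tau, (tau, dev)

    @pytest.mark.parametrize("fn,t0", CASES, ids=["exp", "sin"])
    @pytest.mark.parametrize("lag", [0.01, 0.05])
    @pytest.mark.parametrize("nt", [2, 3, 4])
    def test_beats_one_order_lower_taylor_in_interior(self, fn, t0, lag, nt):
        """|eps_U,nt| < |eps_T,nt-1| away from the small-tau boundary.

        Verified region: tau in [0.25, 1] for both test functions (the sine
        nt=4, lag=0.05 curve still exceeds the lower-order Taylor error just
        below tau ~ 0.22).
        """
        for tau in np.linspace(0.25, 1.0, 16):
            eu = abs(truncation_error(fn, t0, lag, tau, nt, "u"))
            et = abs(truncation_error(fn, t0, 0.0, tau, nt - 1, "taylor"))
            assert eu < et, (tau, eu, et)

    @pytest.mark.parametrize("lag", [0.01, 0.05])
    @pytest.mark.parametrize("nt", [2, 3, 4])
    def test_exponential_beats_lower_order_from_tau_02(self, lag, nt):
        for tau in np.linspace(0.2, 1.0, 17):
            eu = abs(truncation_error(EXP, 0.0, lag, tau, nt, "u"))
            et = abs(truncation_error(EXP, 0.0, 0.0, tau, nt - 1, "taylor"))
            assert eu < et, (tau, eu, et)

    @pytest.mark.parametrize("fn,t0", CASES, ids=["exp", "sin"])
    @pytest.mark.parametrize("nt", [2, 3, 4])
    def test_error_nondecreasing_in_lag(self, fn, t0, nt):
        """At fixed tau the unsynchronized error drifts upward with the lag."""
        errs = [
            abs(truncation_error(fn, t0, lag, 0.05, nt, "u"))
            for lag in (0.001, 0.01, 0.05, 0.1)
        ]
        assert all(b >= a for a, b in zip(errs, errs[1:])), errs

    def test_drift_crosses_lower_order_taylor_curve(self):
        """The lag-0.05 order-3 error curve crosses the order-2 Taylor curve
        near tau ~ 0.065 (agreement within a factor 2 at tau = lag = 0.05)."""
        ratios = []
        taus = np.linspace(0.04, 0.2, 33)
        for tau in taus:
            eu = abs(truncation_error(EXP, 0.0, 0.05, tau, 3, "u"))
            et = abs(truncation_error(EXP, 0.0, 0.0, tau, 2, "taylor"))
            ratios.append(eu / et)
        ratios = np.array(ratios)
        assert ratios[0] > 1.0 and ratios[-1] < 1.0  # a crossing exists
        at_print = abs(truncation_error(EXP, 0.0, 0.05, 0.05, 3, "u")) / abs(
            truncation_error(EXP, 0.0, 0.0, 0.05, 2, "taylor")
        )
        assert 0.5 < at_print < 2.0

    def test_small_increment_errors_negligible(self):
        """With lag 0.01 and tau <= lag the error collapses by ~ two decades
        per retained order (the printed 1e-5 / 1e-7 / 1e-9 ladder, within the
        2x reading of 'about')."""
        for fn, t0 in CASES:
            for nt, bound in [(2, 1e-5), (3, 1e-7), (4, 1e-9)]:
                curve = error_curve(fn, t0, 0.01, nt, detail_grid(0.01))
                assert max_abs_error(curve, (0.0, 0.01)) < 2 * bound


class TestBackwardFiniteDifference:
    def test_weights_first_order(self):
        """Order 1 on two samples is the plain backward difference."""
        assert backward_fd_weights(1) == (1, -1)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_stencil_exact_on_low_degree_polynomials(self, n):
        """2n-point stencil integrates the moment conditions exactly up to
        degree 2n-1."""
        w = backward_fd_weights(n)
        assert len(w) == 2 * n
        for p in range(2 * n):
            moment = sum(wj * (-j) ** p for j, wj in enumerate(w))
            assert moment == (math.factorial(n) if p == n else 0)

    def test_linear_function_exact(self):
        fn = polynomial([3.0, 2.0])
        rec = sample_record(fn, 0.5, 0.1, 2)
        assert backward_fd_derivatives(rec, 1) == pytest.approx(2.0, abs=1e-12)

    def test_second_derivative_accuracy_and_richardson(self):
        """exp'' estimate at T=0.01 within 5e-3; halving T shrinks the error
        by ~ 2^n (order-n accuracy)."""
        errs = {}
        for T in (0.01, 0.005):
            rec = sample_record(EXP, 0.0, T, 4)
            errs[T] = abs(backward_fd_derivatives(rec, 2) - 1.0)
        assert errs[0.01] < 5e-3
        assert errs[0.01] / errs[0.005] == pytest.approx(4.0, rel=0.5)

    def test_sample_requirements(self):
        rec = SampledRecord(0.0, 0.01, tuple(math.exp(-0.01 * j) for j in range(4)))
        with pytest.raises(ArgumentError, match="2n = 6 samples"):
            backward_fd_derivatives(rec, 3)
        with pytest.raises(ArgumentError, match="2\\*nt = 6 samples"):
            backward_fd_predict(rec, 0.1, 3)

    def test_prediction_lag_accounting(self):
        rec = sample_record(EXP, 0.0, 0.01, 6)
        pred = backward_fd_predict(rec, 0.1, 3)
        assert pred.samples_used == 6
        assert pred.acquisition_lag == pytest.approx(0.05)
        assert pred.scheme == "backward-fd"

    def test_linear_prediction_exact(self):
        fn = polynomial([3.0, 2.0])
        rec = sample_record(fn, 0.0, 0.05, 2)
        assert backward_fd_predict(rec, 0.3, 1).value == pytest.approx(
            fn.value(0.3), abs=1e-12
        )

    def test_less_accurate_than_direct_derivative_sensing(self):
        """At matched lag scale the FD-from-samples route loses accuracy in
        addition to paying the (2n-1)T acquisition delay."""
        T = tau = None
        for nt in (2, 3):
            T, tau = 0.01, 0.1
            rec = sample_record(EXP, 0.0, T, 2 * nt)
            fd_err = abs(math.exp(tau) - backward_fd_predict(rec, tau, nt).value)
            u_err = abs(truncation_error(EXP, 0.0, T, tau, nt, "u"))
            assert fd_err > u_err
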