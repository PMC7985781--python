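"""Truncation error vs horizon tau, for several observation lags.

Sweeps the signed error eps = f(t0+tau) - prediction for e^t about t0 = 0,
comparing the unsynchronized expansion (lags 0.001 .. 0.1) with the Taylor
series (lag 0).  Optionally writes a log-scale plot.
"""

import sys

from uexpand import error_curve, exponential, max_abs_error, wide_grid

fn = exponential()
grid = wide_grid()

print("max |error| over tau in [1e-3, 1] (e^t, t0 = 0):")
print(f"{'nt':>3} {'Taylor':>10} " + " ".join(f"t={t:<7g}" for t in (0.001, 0.01, 0.05, 0.1)))
curves = []
for nt in (2, 3, 4):
    taylor = error_curve(fn, 0.0, 0.0, nt, grid, "taylor")
    row = [max_abs_error(taylor, (1e-3, 1.0))]
    curves.append(taylor)
    for lag in (0.001, 0.01, 0.05, 0.1):
        c = error_curve(fn, 0.0, lag, nt, grid, "u")
        curves.append(c)
        row.append(max_abs_error(c, (1e-3, 1.0)))
    print(f"{nt:>3} " + " ".join(f"{v:>9.2e}" for v in row))
# For small lags the unsynchronized error tracks the Taylor error of the
# same order; as the lag grows it drifts toward lower-order Taylor behavior.

if "--plot" in sys.argv:
    from uexpand.error_analysis import plot_error_curves

    plot_error_curves(curves, path="error_curves.png")
    print("wrote error_curves.png")
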