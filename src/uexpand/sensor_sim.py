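"""Synthetic unsynchronized sensor streams and rolling-horizon prediction.

Emulates the biological setting the expansion is built for: an array of
receptors reports a physiological quantity and its first N time derivatives,
each at its own detection time, and a downstream predictor extrapolates the
quantity a horizon ``tau`` ahead.  Observation noise is additive i.i.d.
Gaussian on each observed derivative value — the minimal stand-in for
receptor variability; ``sigma = 0`` recovers exact observations.

Schedules per base time:

* uniform — ``t_n = t0 - n*lag``: higher derivatives are progressively
  staler (the most unfavorable regular arrangement);
* jittered — the uniform times perturbed by ``U(-width/2, width/2)``, so the
  maximum inter-observation gap never exceeds ``lag + width``;
* explicit — caller-supplied offsets relative to ``t0``.

All randomness flows through one seeded ``numpy`` generator, so a stream is
fully reproducible from its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .error_analysis import TestFunction, get_function
from .predictor import DerivativeObservationSet, u_predict


@dataclass(frozen=True)
class UniformSpec:
    """Uniform-lag schedule: order-n observation at ``t0 - n*lag``."""

    lag: float
    N: int


@dataclass(frozen=True)
class JitteredSpec:
    """Uniform-lag schedule with i.i.d. uniform jitter of total ``width``."""

    lag: float
    N: int
    width: float


@dataclass(frozen=True)
class ExplicitSpec:
    """Fixed offsets: order-n observation at ``t0 + offsets[n-1]``."""

    offsets: tuple


@dataclass(frozen=True)
class SensorStream:
    """A reproducible sequence of unsynchronized observation sets."""

    function: TestFunction
    spec: object
    sigma: float
    seed: int
    base_times: np.ndarray
    observation_sets: tuple = field(repr=False)  # one DerivativeObservationSet per t0

    def __len__(self) -> int:
        return len(self.observation_sets)


def _times_for(spec, t0: float, rng: np.random.Generator) -> tuple:
    if isinstance(spec, UniformSpec):
        return tuple(t0 - n * spec.lag for n in range(1, spec.N + 1))
    if isinstance(spec, JitteredSpec):
        jit = rng.uniform(-spec.width / 2, spec.width / 2, size=spec.N)
        return tuple(t0 - n * spec.lag + jit[n - 1] for n in range(1, spec.N + 1))
    if isinstance(spec, ExplicitSpec):
        return tuple(t0 + off for off in spec.offsets)
    raise ArgumentError(f"unknown schedule spec {spec!r}")


def generate_stream(
    trajectory,
    spec,
    sigma: float = 0.0,
    seed: int = 0,
    span: Sequence[float] = (0.0,),
) -> SensorStream:
    """Generate one observation set per base time in ``span``.

    ``trajectory`` is a :class:`~uexpand.error_analysis.TestFunction` or the
    name of a built-in one (``"exp"``, ``"sin"``).  With ``sigma = 0`` every
    stored value is the trajectory's exact derivative at its stored time.
    """
    if isinstance(trajectory, str):
        trajectory = get_function(trajectory)
    if sigma < 0:
        raise ArgumentError(f"noise sigma must be nonnegative, got {sigma}")
    rng = np.random.default_rng(seed)
    base_times = np.asarray(list(span), dtype=float)
    sets = []
    for t0 in base_times:
        times = _times_for(spec, t0, rng)
        noise_f0 = sigma * rng.standard_normal() if sigma > 0 else 0.0
        obs = []
        for n, tn in enumerate(times, start=1):
            eta = sigma * rng.standard_normal() if sigma > 0 else 0.0
            obs.append((n, tn, trajectory.derivative(n, tn) + eta))
        sets.append(
            DerivativeObservationSet(t0, trajectory.value(t0) + noise_f0, tuple(obs))
        )
    return SensorStream(trajectory, spec, sigma, seed, base_times, tuple(sets))


@dataclass(frozen=True)
class PredictionExperimentResult:
    """Per-step prediction records plus their summary statistics."""

    tau: float
    nt: int
    records: object  # pandas.DataFrame: t0, tau, truth, prediction, error
    max_abs_error: float
    rms_error: float

    def summary(self) -> dict:
        return {
            "tau": self.tau,
            "nt": self.nt,
            "steps": int(len(self.records)),
            "max_abs_error": self.max_abs_error,
            "rms_error": self.rms_error,
        }


def rolling_prediction(stream: SensorStream, tau: float, nt: int) -> PredictionExperimentResult:
    """Predict ``tau`` ahead at every base time and score against the truth."""
    import pandas as pd

    if len(stream) == 0:
        raise ArgumentError("stream is empty")
    if any(s.N < nt for s in stream.observation_sets):
        raise ArgumentError(
            f"stream provides fewer than nt={nt} derivative orders per step"
        )
    rows = []
    for obs in stream.observation_sets:
        pred = u_predict(obs, tau, nt)
        truth = stream.function.value(obs.t0 + tau)
        rows.append(
            {
                "t0": obs.t0,
                "tau": tau,
                "truth": truth,
                "prediction": pred.value,
                "error": truth - pred.value,
            }
        )
    records = pd.DataFrame(rows)
    errs = records["error"].to_numpy()
    return PredictionExperimentResult(
        tau=tau,
        nt=nt,
        records=records,
        max_abs_error=float(np.max(np.abs(errs))),
        rms_error=float(math.sqrt(np.mean(errs**2))),
    )
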