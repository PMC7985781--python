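"""Readers and writers for schedules, observations, tables, curves, streams.

Conventions: JSON carries full-precision floats (shortest round-trip repr);
CSV numerics are written with 17 significant digits; exact rationals are
serialized as ``"num/den"`` strings.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

from .coefficients import CoefficientTable, DetectionSchedule, UniformLagSchedule
from .errors import ArgumentError
from .error_analysis import TruncationErrorCurve
from .predictor import DerivativeObservationSet, TruncatedPrediction
from .sensor_sim import PredictionExperimentResult, SensorStream


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _load(obj):
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            return json.load(fh)
    return obj


# ---------------------------------------------------------------------------
# schedules

def schedule_from_json(obj) -> DetectionSchedule:
    """Build a schedule from ``{"t0", "times"}`` or ``{"t0", "lag", "N"}``."""
    d = _load(obj)
    if "times" in d:
        return DetectionSchedule(float(d["t0"]), tuple(float(x) for x in d["times"]))
    if "lag" in d:
        return UniformLagSchedule(float(d["t0"]), float(d["lag"]), int(d["N"]))
    raise ArgumentError("schedule JSON needs either 'times' or 'lag'+'N'")


def schedule_to_json(schedule: DetectionSchedule) -> dict:
    if isinstance(schedule, UniformLagSchedule):
        return {"t0": schedule.t0, "lag": schedule.lag, "N": schedule.N}
    return {"t0": schedule.t0, "times": list(schedule.times)}


# ---------------------------------------------------------------------------
# observation sets

def observations_from_json(obj) -> DerivativeObservationSet:
    d = _load(obj)
    obs = tuple(
        (int(o["n"]), float(o["t"]), float(o["value"]))
        for o in sorted(d["observations"], key=lambda o: int(o["n"]))
    )
    return DerivativeObservationSet(float(d["t0"]), float(d["f0"]), obs)


def observations_to_json(obs: DerivativeObservationSet) -> dict:
    return {
        "t0": obs.t0,
        "f0": obs.f0,
        "observations": [
            {"n": n, "t": t, "value": v} for n, t, v in obs.observations
        ],
    }


def observations_from_csv(path) -> DerivativeObservationSet:
    """Three-column CSV ``n,t,value``; the row with ``n = 0`` carries ``t0, f(t0)``."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"n", "t", "value"} - set(df.columns)
    if missing:
        raise ArgumentError(f"observation CSV lacks columns {sorted(missing)}")
    base = df[df["n"] == 0]
    if len(base) != 1:
        raise ArgumentError("observation CSV needs exactly one n=0 row with t0 and f(t0)")
    rest = df[df["n"] > 0].sort_values("n")
    obs = tuple(
        (int(r.n), float(r.t), float(r.value)) for r in rest.itertuples()
    )
    return DerivativeObservationSet(
        float(base["t"].iloc[0]), float(base["value"].iloc[0]), obs
    )


def observations_to_csv(obs: DerivativeObservationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("n,t,value\n")
        fh.write(f"0,{_fmt(obs.t0)},{_fmt(obs.f0)}\n")
        for n, t, v in obs.observations:
            fh.write(f"{n},{_fmt(t)},{_fmt(v)}\n")


def prediction_to_json(pred: TruncatedPrediction) -> dict:
    return {"scheme": pred.scheme, "nt": pred.nt, "tau": pred.tau, "value": pred.value}


# ---------------------------------------------------------------------------
# coefficient tables

def coefficient_table_to_csv(table: CoefficientTable, path) -> None:
    """Columns ``n,k,p_nk`` plus ``c_nk,t_power`` for uniform-lag tables."""
    uniform = table.rational_entries is not None
    with open(path, "w") as fh:
        fh.write("n,k,p_nk,c_nk,t_power\n" if uniform else "n,k,p_nk\n")
        for (n, k), p in table.items():
            if uniform:
                c = table.c(n, k)
                fh.write(f"{n},{k},{_fmt(p)},{c.numerator}/{c.denominator},{n - k}\n")
            else:
                fh.write(f"{n},{k},{_fmt(p)}\n")


# ---------------------------------------------------------------------------
# error curves

def curves_to_csv(curves, path) -> None:
    """Long-format CSV: function,t0,t,nt,scheme,tau,error."""
    if isinstance(curves, TruncationErrorCurve):
        curves = [curves]
    with open(path, "w") as fh:
        fh.write("function,t0,t,nt,scheme,tau,error\n")
        for c in curves:
            for tau, err in zip(c.taus, c.errors):
                fh.write(
                    f"{c.function_name},{_fmt(c.t0)},{_fmt(c.lag)},{c.nt},"
                    f"{c.scheme},{_fmt(tau)},{_fmt(err)}\n"
                )


# ---------------------------------------------------------------------------
# streams and experiments

def stream_to_jsonl(stream: SensorStream, path) -> None:
    """One observation set per line."""
    with open(path, "w") as fh:
        for obs in stream.observation_sets:
            fh.write(json.dumps(observations_to_json(obs)) + "\n")


def stream_sets_from_jsonl(path) -> tuple:
    with open(path) as fh:
        return tuple(observations_from_json(json.loads(line)) for line in fh if line.strip())


def result_to_files(result: PredictionExperimentResult, csv_path, summary_path) -> None:
    result.records.to_csv(csv_path, index=False, float_format="%.17g")
    with open(summary_path, "w") as fh:
        json.dump(result.summary(), fh, indent=2)
        fh.write("\n")


def fraction_from_string(s: str) -> Fraction:
    return Fraction(s)
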