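"""Analytics for the 12 x 25 m maximal-effort critical-speed swim test.

The test is 12 consecutive all-out 25 m efforts separated by 5 s of passive
rest.  From the lap times it derives: peak speed (mean speed of the first
effort), critical speed (CS; mean speed of the slowest two efforts among the
final four — the fatigued plateau), percent drop-off from peak to CS, a
three-parameter exponential speed-time model S(t) = a*e^(b*t) + c fitted to
lap speeds at cumulative-swim-time midpoints, and D' — the finite distance
capacity available above CS, computed as the area between the fitted curve
and the CS line over the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

N_LAPS = 12
LAP_DISTANCE_DEFAULT = 25.0


class PacingWarning(UserWarning):
    """The lap profile contradicts an all-out pacing strategy."""


class ModelFitError(RuntimeError):
    def __init__(self, msg: str, params=None, sse: float = np.nan):
        super().__init__(msg)
        self.params = params
        self.sse = sse


@dataclass
class SwimTestRecord:
    """One swimmer's 12 x 25 m test."""

    lap_times: np.ndarray  # 12 durations, seconds
    lap_distance: float = LAP_DISTANCE_DEFAULT
    rest_between: float = 5.0  # informational; rests are not swim time
    swimmer_id: str = ""
    stroke: str = "freestyle"

    def __post_init__(self) -> None:
        self.lap_times = np.asarray(self.lap_times, dtype=float)
        if self.lap_times.size != N_LAPS:
            raise ValueError(f"expected {N_LAPS} lap times, got {self.lap_times.size}")
        if (self.lap_times <= 0).any():
            raise ValueError("lap times must be positive")
        if self.lap_distance <= 0:
            raise ValueError("lap distance must be positive")

    @property
    def speeds(self) -> np.ndarray:
        return self.lap_distance / self.lap_times

    @property
    def t1(self) -> float:
        """Cumulative swim time at the end of the twelfth effort (rests
        excluded)."""
        return float(self.lap_times.sum())

    @property
    def midpoint_times(self) -> np.ndarray:
        """Cumulative swim time at each lap's midpoint."""
        ends = np.cumsum(self.lap_times)
        return ends - self.lap_times / 2.0


@dataclass
class CritSpeedResult:
    peak_speed: float
    cs: float
    dropoff_pct: float
    model: Tuple[float, float, float]  # (a, b, c) of S(t) = a e^{bt} + c
    t1: float
    d_prime: float
    d_prime_discrete: float
    decaying: bool  # b < 0

    def to_row(self) -> dict:
        a, b, c = self.model
        return {
            "peak_speed": self.peak_speed,
            "cs": self.cs,
            "dropoff_pct": self.dropoff_pct,
            "a": a,
            "b": b,
            "c": c,
            "t1": self.t1,
            "d_prime": self.d_prime,
        }


def compute_peak_speed(record: SwimTestRecord) -> float:
    """Mean speed of the first 25 m effort."""
    return record.lap_distance / record.lap_times[0]


def compute_critical_speed(record: SwimTestRecord) -> float:
    """Mean speed of the slowest two efforts within the final four.

    Ties among the final four resolve by sorting times descending and taking
    the first two; only the time values matter, so the outcome is
    tie-invariant.
    """
    final_four = record.lap_times[-4:]
    slowest_two = np.sort(final_four)[::-1][:2]
    return float(np.mean(record.lap_distance / slowest_two))


def compute_dropoff(peak: float, cs: float) -> float:
    """Percent difference between peak speed and CS: 100 (peak - cs) / peak.

    A CS above peak (first lap not the fastest phase) yields a negative
    value plus a data-quality warning rather than an error.
    """
    if peak <= 0:
        raise ValueError("peak speed must be positive")
    if cs > peak:
        warnings.warn(
            "CS exceeds peak speed; check pacing (test should be all-out from lap 1)",
            PacingWarning,
            stacklevel=2,
        )
    return 100.0 * (peak - cs) / peak


def fit_speed_time_model(
    record: SwimTestRecord,
    include_rests: bool = False,
    max_iter: int = 500,
) -> Tuple[float, float, float]:
    """Nonlinear least squares for S(t) = a e^{bt} + c on lap speeds.

    Time points are cumulative swim time at lap midpoints (rests excluded
    unless ``include_rests``).  Initialized at a = S1 - S12, b = -1/t1,
    c = S12; converges when the relative SSE change drops below 1e-10.
    """
    speeds = record.speeds
    if include_rests:
        ends = np.cumsum(record.lap_times) + record.rest_between * np.arange(N_LAPS)
        t = ends - record.lap_times / 2.0
    else:
        t = record.midpoint_times
    if len(np.unique(t)) < 3:
        raise ModelFitError("need >= 3 distinct time points")

    s1, s12 = speeds[0], speeds[-1]
    x0 = np.array([s1 - s12, -1.0 / record.t1, s12])

    def residuals(params):
        a, b, c = params
        return a * np.exp(b * t) + c - speeds

    res = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-12, ftol=1e-10, gtol=1e-12,
        max_nfev=max_iter * 4,
    )
    if not res.success:
        raise ModelFitError(
            f"speed-time model did not converge: {res.message}",
            params=tuple(res.x),
            sse=float(np.sum(res.fun**2)),
        )
    a, b, c = res.x
    return float(a), float(b), float(c)


def compute_d_prime(
    model: Tuple[float, float, float], cs: float, t1: float
) -> float:
    """D' (meters): area between the fitted speed curve and CS over [0, t1].

    D' = integral of max(S(t) - CS, 0) dt with S(t) = a e^{bt} + c.  In
    closed form, with t_u = min(t1, t*) where t* = (1/b) ln((CS - c)/a) is
    the time the decaying curve crosses CS (when it does):

        D' = (a/b) (e^{b t_u} - 1) + (c - CS) t_u

    Requires b < 0 (a decaying model).
    """
    a, b, c = model
    if b >= 0:
        raise ValueError(f"speed-time model must decay (b < 0), got b={b}")
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    if a == 0:
        return max(c - cs, 0.0) * t1
    # crossing time of S(t) = CS, if inside (0, t1)
    ratio = (cs - c) / a
    t_u = t1
    if a > 0 and 0 < ratio < 1:  # curve starts above CS and decays through it
        t_star = np.log(ratio) / b
        t_u = min(t1, t_star)
    elif a > 0 and ratio >= 1:
        return 0.0  # curve starts at or below CS
    d = (a / b) * (np.exp(b * t_u) - 1.0) + (c - cs) * t_u
    return float(max(d, 0.0))


def compute_d_prime_discrete(record: SwimTestRecord, cs: float) -> float:
    """Lap-wise discrete variant: sum over laps of (speed - CS)+ x lap time."""
    excess = np.clip(record.speeds - cs, 0.0, None)
    return float(np.sum(excess * record.lap_times))


def analyze_record(record: SwimTestRecord) -> CritSpeedResult:
    """Full per-swimmer analysis of one 12 x 25 m test."""
    peak = compute_peak_speed(record)
    cs = compute_critical_speed(record)
    dropoff = compute_dropoff(peak, cs)
    a, b, c = fit_speed_time_model(record)
    decaying = b < 0
    if decaying:
        d_prime = compute_d_prime((a, b, c), cs, record.t1)
    else:
        warnings.warn(
            "fitted speed-time model does not decay; D' from discrete lap areas",
            PacingWarning,
            stacklevel=2,
        )
        d_prime = compute_d_prime_discrete(record, cs)
    return CritSpeedResult(
        peak_speed=peak,
        cs=cs,
        dropoff_pct=dropoff,
        model=(a, b, c),
        t1=record.t1,
        d_prime=d_prime,
        d_prime_discrete=compute_d_prime_discrete(record, cs),
        decaying=decaying,
    )


def read_lap_times_csv(path) -> list:
    """Read swim-test records from CSV (swimmer_id, stroke, lap_index,
    lap_time_s)."""
    df = pd.read_csv(path)
    records = []
    for (sid, stroke), grp in df.groupby(["swimmer_id", "stroke"], sort=True):
        grp = grp.sort_values("lap_index")
        records.append(
            SwimTestRecord(
                lap_times=grp["lap_time_s"].to_numpy(),
                swimmer_id=str(sid),
                stroke=str(stroke),
            )
        )
    return records


def analyze_csv(path, out_path=None) -> pd.DataFrame:
    """Analyze every swimmer in a lap-times CSV; optionally write results."""
    rows = []
    for rec in read_lap_times_csv(path):
        res = analyze_record(rec)
        row = {"swimmer_id": rec.swimmer_id, "stroke": rec.stroke}
        row.update(res.to_row())
        rows.append(row)
    out = pd.DataFrame(rows)
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
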