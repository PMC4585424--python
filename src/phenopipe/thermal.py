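"""Thermal-time compensation of rates and durations.

Development rate responds to temperature through a modified Johnson
thermodynamic response

    F(T) = A * T * exp(-dHa / (R*T)) / (1 + exp(-dHd / (R*T)) ** (alpha * (1 - T/T0)))

with T in Kelvin.  A rate measured at temperature T is expressed as the
equivalent rate at 20 degC by multiplying with F(20)/F(T); a duration is
expressed in equivalent days at 20 degC (d20) by integrating F(T)/F(20)
over the logged temperature series.  The scaling coefficient A cancels in
every ratio.

By default the same enthalpy appears in both exponents, as in the printed
form of the response; a distinct high-temperature enthalpy can be supplied
through the ``dHd`` config hook for the two-enthalpy formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import R_GAS, T_REF_K, TemperatureResponseParams

__all__ = [
    "response",
    "compensate_rate",
    "TemperatureSeries",
    "thermal_time",
    "thermal_axis",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """A logged greenhouse temperature series.

    ``timestamps_h`` are hours since sowing (strictly increasing);
    ``temps_C`` are air temperatures in degC within (-20, 60) sanity
    bounds.  Integration treats the temperature as piecewise constant over
    each logger interval, matching the data cadence.
    """

    timestamps_h: np.ndarray
    temps_C: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_h, dtype=float)
        x = np.asarray(self.temps_C, dtype=float)
        object.__setattr__(self, "timestamps_h", t)
        object.__setattr__(self, "temps_C", x)
        if t.size < 2:
            raise ValueError("temperature series needs at least 2 points")
        if t.size != x.size:
            raise ValueError("timestamps and temperatures differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any((x <= -20) | (x >= 60)):
            raise ValueError("temperatures outside (-20, 60) degC sanity bounds")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        return cls(df["timestamp_h"].to_numpy(), df["temp_C"].to_numpy())


def _log_response(T_C, p: TemperatureResponseParams):
    """log F(T) evaluated stably (the high-T power term can overflow)."""
    T_K = np.asarray(T_C, dtype=float) + 273.15
    if np.any(T_K <= 0):
        raise ValueError("temperature below absolute zero")
    num = np.log(p.A) + np.log(T_K) - p.dHa / (R_GAS * T_K)
    # denominator 1 + [exp(-dHd/(R T))]^(alpha (1 - T/T0)) in log space
    expo = -p.dHd_effective / (R_GAS * T_K) * p.alpha * (1.0 - T_K / p.T0)
    logF = num - np.logaddexp(0.0, expo)
    if not np.all(np.isfinite(logF)):
        bad = np.asarray(T_C)[~np.isfinite(np.atleast_1d(logF))]
        raise FloatingPointError(f"non-finite temperature response at T={bad}")
    return logF


def response(T_C, p: TemperatureResponseParams):
    """Temperature response F(T) with T in degC; strictly positive."""
    out = np.exp(_log_response(T_C, p))
    return float(out) if np.ndim(out) == 0 else out


def compensate_rate(J, T_C, p: TemperatureResponseParams):
    """Express a rate measured at T as the equivalent rate at 20 degC.

    Returns J * F(20)/F(T); independent of the scaling coefficient A.
    """
    ratio = np.exp(_log_response(20.0, p) - _log_response(T_C, p))
    if np.any(~np.isfinite(np.atleast_1d(ratio))) or np.any(np.atleast_1d(ratio) == np.inf):
        raise FloatingPointError(f"temperature response underflow at T={T_C}")
    out = np.asarray(J, dtype=float) * ratio
    return float(out) if np.ndim(out) == 0 else out


def thermal_time(series: TemperatureSeries, p: TemperatureResponseParams,
                 t_start_h: float, t_end_h: float) -> float:
    """Equivalent duration at 20 degC (same unit as the timestamps, hours).

    Integrates F(T)/F(20) piecewise-constant over the logger intervals
    covered by [t_start_h, t_end_h]; additive over contiguous windows.
    """
    t = series.timestamps_h
    if t_start_h < t[0] or t_end_h > t[-1]:
        raise ValueError(
            f"window [{t_start_h}, {t_end_h}] outside series span [{t[0]}, {t[-1]}]"
        )
    if t_end_h < t_start_h:
        raise ValueError("t_end must be >= t_start")
    ratio = np.exp(_log_response(series.temps_C[:-1], p) - _log_response(20.0, p))
    left = np.clip(t[:-1], t_start_h, t_end_h)
    right = np.clip(t[1:], t_start_h, t_end_h)
    return float(np.sum((right - left) * ratio))


def thermal_axis(series: TemperatureSeries, p: TemperatureResponseParams,
                 sample_days: np.ndarray) -> np.ndarray:
    """Cumulative thermal time (d20) at each calendar sampling day.

    This monotone increasing mapping is the x-axis for all growth fitting.
    Day 0 of the axis is the start of the temperature record (sowing).
    """
    sample_days = np.asarray(sample_days, dtype=float)
    order = np.argsort(sample_days)
    t0 = series.timestamps_h[0]
    out = np.empty_like(sample_days)
    prev_h, acc = t0, 0.0
    for i in order:
        h = sample_days[i] * 24.0
        acc += thermal_time(series, p, prev_h, h)
        out[i] = acc / 24.0
        prev_h = h
    return out
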