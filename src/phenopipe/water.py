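"""Gravimetric water use: pot balance, soil water potential, transpiration.

Every second day each pot is weighed and watered back to its treatment's
target soil water potential.  Weight change between waterings, corrected
for the increase in plant fresh weight (modelled from the images) and for
soil-surface evaporation (measured on pots carrying artificial plants),
gives the plant's transpiration.  Gravimetric soil water content converts
to soil water potential through a Van Genuchten water-release curve
fitted to pressure-chamber observations:

    theta(psi) = theta_r + (theta_s - theta_r) * [1 + (a*|psi|)^n]^(-m),
    m = 1 - 1/n

with theta in g water per g dry soil and psi in MPa (negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "WaterReleaseParams",
    "water_content_from_potential",
    "soil_water_potential",
    "fit_water_release",
    "soil_water_content",
    "evaporation_estimates",
    "water_balance",
    "transpiration_traits",
    "relative_response",
]


@dataclass(frozen=True)
class WaterReleaseParams:
    """Van Genuchten parameters: residual/saturated gravimetric content,
    inverse-potential scale a (MPa^-1) and shape n (>1); m = 1 - 1/n."""

    theta_r: float
    theta_s: float
    a_vg: float
    n_vg: float

    def __post_init__(self) -> None:
        if not (0 <= self.theta_r < self.theta_s):
            raise ValueError("need 0 <= theta_r < theta_s")
        if self.a_vg <= 0 or self.n_vg <= 1:
            raise ValueError("need a_vg > 0 and n_vg > 1")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg


def water_content_from_potential(psi_MPa, p: WaterReleaseParams):
    """Forward Van Genuchten curve theta(psi); psi <= 0 in MPa."""
    psi = np.abs(np.asarray(psi_MPa, dtype=float))
    theta = p.theta_r + (p.theta_s - p.theta_r) * (
        1.0 + (p.a_vg * psi) ** p.n_vg) ** (-p.m_vg)
    return float(theta) if np.ndim(theta) == 0 else theta


def soil_water_potential(theta, p: WaterReleaseParams, return_flags: bool = False):
    """Closed-form inversion of the water-release curve (psi in MPa, <= 0).

    Values outside (theta_r, theta_s] within a 1% (of theta_s - theta_r)
    measurement-noise tolerance are clamped with a flag; beyond that an
    error is raised.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    span = p.theta_s - p.theta_r
    tol = 0.01 * span
    flags = np.zeros(theta.shape, dtype=bool)
    if np.any(theta > p.theta_s + tol) or np.any(theta < p.theta_r - tol):
        bad = theta[(theta > p.theta_s + tol) | (theta < p.theta_r - tol)]
        raise ValueError(f"water content {bad} outside fitted curve range "
                         f"({p.theta_r:.4f}, {p.theta_s:.4f}] beyond 1% tolerance")
    hi = theta > p.theta_s
    lo = theta <= p.theta_r
    flags |= hi | lo
    th = theta.copy()
    th[hi] = p.theta_s
    th[lo] = p.theta_r + tol
    Se = (th - p.theta_r) / span
    psi = np.where(
        Se >= 1.0, 0.0,
        -(1.0 / p.a_vg) * (Se ** (-1.0 / p.m_vg) - 1.0) ** (1.0 / p.n_vg),
    )
    if return_flags:
        return (psi if psi.size > 1 else float(psi[0]),
                flags if flags.size > 1 else bool(flags[0]))
    return psi if psi.size > 1 else float(psi[0])


def fit_water_release(theta_obs, psi_obs) -> WaterReleaseParams:
    """Least-squares fit of the release curve to (theta, psi) observations.

    Observations should span wet to dry (around -0.01 to -1.6 MPa).
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    psi_obs = np.asarray(psi_obs, dtype=float)
    if theta_obs.size < 6:
        raise ValueError("need at least 6 water-release observations")

    def f(psi, theta_r, theta_s, a, n):
        return water_content_from_potential(
            psi, WaterReleaseParams(theta_r, theta_s, a, n))

    p0 = (0.5 * theta_obs.min(), theta_obs.max(),
          1.0 / max(np.median(np.abs(psi_obs)), 1e-3), 1.5)
    try:
        popt, _ = curve_fit(
            f, psi_obs, theta_obs, p0=p0,
            bounds=([0.0, 1e-6, 1e-6, 1.0 + 1e-6],
                    [theta_obs.max(), 2.0 * theta_obs.max(), 1e4, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"water-release fit did not converge: {exc}; "
            f"theta range {theta_obs.min():.3f}-{theta_obs.max():.3f}"
        ) from exc
    return WaterReleaseParams(*[float(x) for x in popt])


def soil_water_content(weight_g, tare_g: float, dry_soil_g: float,
                       plant_weight_g):
    """Gravimetric water content from a pot weight.

    water mass = pot weight - tare - dry soil - modelled fresh plant
    weight (the population-mean modelled weight at that time); theta is
    water mass per unit dry soil.
    """
    water = (np.asarray(weight_g, dtype=float) - tare_g - dry_soil_g
             - np.asarray(plant_weight_g, dtype=float))
    if np.any(water < 0):
        raise ValueError("negative water mass: inconsistent tare/dry-soil inputs")
    theta = water / dry_soil_g
    return float(theta) if np.ndim(theta) == 0 else theta


def evaporation_estimates(pot_logs: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment, per-interval soil-evaporation from artificial pots.

    Water loss of an artificial pot over an interval is
    weight_after[i] - weight_before[i+1] (no plant correction).  Returns a
    frame with columns treatment, t_start, t_end, evaporation_g, carried
    (True where a missing interval reused the previous estimate).
    """
    art = pot_logs[pot_logs["is_artificial"]]
    if art.empty:
        raise ValueError("no artificial-plant pots in the log")
    rows = []
    for (trt, pid), grp in art.groupby(["treatment", "plant_id"]):
        g = grp.sort_values("time_d")
        t = g["time_d"].to_numpy(dtype=float)
        loss = g["weight_after_g"].to_numpy()[:-1] - g["weight_before_g"].to_numpy()[1:]
        for i in range(t.size - 1):
            rows.append((trt, t[i], t[i + 1], loss[i]))
    df = pd.DataFrame(rows, columns=["treatment", "t_start", "t_end", "loss"])
    out = (df.groupby(["treatment", "t_start", "t_end"], as_index=False)["loss"]
             .mean().rename(columns={"loss": "evaporation_g"}))
    out["carried"] = False
    return out


def _lookup_evap(evap: pd.DataFrame, treatment: str, t_start: float):
    """Evaporation for one interval, carrying the previous estimate
    forward (flagged) when the interval is missing."""
    sub = evap[evap["treatment"] == treatment]
    exact = sub[np.isclose(sub["t_start"], t_start)]
    if len(exact):
        return float(exact["evaporation_g"].iloc[0]), False
    prev = sub[sub["t_start"] < t_start]
    if len(prev):
        return float(prev.sort_values("t_start")["evaporation_g"].iloc[-1]), True
    return 0.0, True


def water_balance(pot_logs: pd.DataFrame, release: WaterReleaseParams,
                  tare_g: float, dry_soil_g: float,
                  plant_weight) -> pd.DataFrame:
    """Per-plant per-interval water balance records.

    ``plant_weight(plant_id, treatment, time_d)`` returns the modelled
    fresh plant weight (g) at a calendar day — normally the treatment
    population mean, optionally the plant's own modelled weight; it
    corrects pot weights for plant growth.  Output columns: plant_id, treatment,
    t_start, t_end, water_loss_g, evaporation_g, transpiration_g,
    theta_start, theta_end, psi_start, psi_end, psi_mean, floored,
    evap_carried, theta_clamped.
    """
    evap = evaporation_estimates(pot_logs)
    plants = pot_logs[~pot_logs["is_artificial"]]
    rows = []
    for (pid, trt), grp in plants.groupby(["plant_id", "treatment"]):
        g = grp.sort_values("time_d")
        t = g["time_d"].to_numpy(dtype=float)
        wb = g["weight_before_g"].to_numpy(dtype=float)
        wa = g["weight_after_g"].to_numpy(dtype=float)
        pw = np.asarray([plant_weight(pid, trt, ti) for ti in t], dtype=float)
        stored_before = wb - tare_g - dry_soil_g - pw
        stored_after = wa - tare_g - dry_soil_g - pw
        th_before = stored_before / dry_soil_g
        th_after = stored_after / dry_soil_g
        psi_before, fl_b = soil_water_potential(th_before, release, return_flags=True)
        psi_after, fl_a = soil_water_potential(th_after, release, return_flags=True)
        psi_before = np.atleast_1d(psi_before)
        psi_after = np.atleast_1d(psi_after)
        fl_b = np.atleast_1d(fl_b)
        fl_a = np.atleast_1d(fl_a)
        for i in range(t.size - 1):
            loss = stored_after[i] - stored_before[i + 1]
            ev, carried = _lookup_evap(evap, trt, t[i])
            transp = loss - ev
            floored = transp < 0
            rows.append({
                "plant_id": pid, "treatment": trt,
                "t_start": t[i], "t_end": t[i + 1],
                "water_loss_g": loss, "evaporation_g": ev,
                "transpiration_g": max(transp, 0.0),
                "theta_start": th_after[i], "theta_end": th_before[i + 1],
                "psi_start": psi_after[i], "psi_end": psi_before[i + 1],
                "psi_mean": 0.5 * (psi_after[i] + psi_before[i + 1]),
                "floored": bool(floored),
                "evap_carried": carried,
                "theta_clamped": bool(fl_a[i] or fl_b[i + 1]),
            })
    return pd.DataFrame(rows)


def transpiration_traits(balance: pd.DataFrame, thermal_of_day,
                         biomass_fit, leaf_area_fit,
                         window=(35.0, 50.0)):
    """Window-average transpiration traits for one plant.

    ``balance`` holds that plant's water-balance intervals on the calendar
    axis; ``thermal_of_day`` maps calendar day to thermal day.  Intervals
    partially overlapping the thermal window contribute pro rata so that
    totals are conserved.  Returns a dict with TR (g per d20), TR_area
    (g mm^-2 per d20), WUE (g g^-1), TR_cal (g per calendar day, flagged
    variant), psi_mean (time-weighted MPa) and QC fields.  By
    construction WUE * TR equals the biomass Growth_AVE over the same
    window.
    """
    from .growth import predict

    a, b = float(window[0]), float(window[1])
    total, cal_days, psi_wsum, wsum = 0.0, 0.0, 0.0, 0.0
    n_overlap = 0
    for rec in balance.itertuples():
        u = float(thermal_of_day(rec.t_start))
        w = float(thermal_of_day(rec.t_end))
        if w <= a or u >= b:
            continue
        frac = (min(w, b) - max(u, a)) / (w - u)
        total += rec.transpiration_g * frac
        cal_days += (rec.t_end - rec.t_start) * frac
        dur = (min(w, b) - max(u, a))
        psi_wsum += rec.psi_mean * dur
        wsum += dur
        n_overlap += 1
    if n_overlap < 2:
        raise ValueError("need >= 2 water-balance intervals overlapping the window")
    length = b - a
    tr = total / length
    grid = np.arange(a, b + 1e-9, 0.1)
    mean_la = float(np.trapezoid(predict(leaf_area_fit, grid), grid) / length)
    d_biomass = float(predict(biomass_fit, b) - predict(biomass_fit, a))
    out = {
        "TR": tr,
        "TR_area": tr / mean_la if mean_la > 0 else np.nan,
        "TR_cal": total / cal_days if cal_days > 0 else np.nan,
        "total_transpiration_g": total,
        "psi_mean": psi_wsum / wsum if wsum > 0 else np.nan,
        "wue_undefined": total <= 0,
        "WUE": d_biomass / total if total > 0 else np.nan,
    }
    return out


def relative_response(value_ww, value_d, psi_ww, psi_d):
    """Relative response to soil water potential, per MPa:
    (value_drought - value_ww) / (psi_drought - psi_ww).

    Returns (response, undefined_flag); undefined when the two potentials
    differ by less than 0.005 MPa.
    """
    dpsi = psi_d - psi_ww
    if abs(dpsi) < 0.005:
        return float("nan"), True
    return (value_d - value_ww) / dpsi, False
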