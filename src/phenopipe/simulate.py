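"""Synthetic imaging-platform experiment with known ground truth.

Generates every data stream the analysis pipeline consumes — RIL
genotypes with planted QTL effects, per-plant growth trajectories on the
thermal-time axis, side/top pixel areas, pot weighing/watering logs with
artificial-plant evaporation pots, a greenhouse temperature log, a
destructive calibration harvest and water-release-curve observations —
so that every pipeline stage has a recoverable truth.

The default configuration reproduces the platform study conditions: 150
lines x 2 replicates x 2 watering regimes (watered back every second day
to -0.02 MPa or -0.05 MPa), imaging every second day from 3 weeks after
sowing to flowering, a 17-25 degC daily temperature sinusoid, two
artificial-plant pots per treatment, and a parental destructive harvest
twice a week.

Generative model, per plant: a latent logistic development curve
S(t) = 1/(1 + exp(-K (t - t0))) on thermal time drives the two projected
areas, side = c1 * S and top = c2 * S^0.9 (the top view saturates
slightly as leaves overlap).  The three biological traits are fixed
population-level polynomials of the two areas (the same second-order
forms the calibration stage is meant to recover).  Transpiration over a
watering interval is proportional to leaf area times an evaporative
demand that fluctuates slowly day to day; soil evaporation depends on the
post-watering water content, hence is lower in the drier regime.  Line
effects, planted QTL effects (including two phenology loci acting on t0)
and replicate-level variation enter the latent parameters additively.

Ground truth is written under a ``truth/`` prefix that the analysis
pipeline never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import CameraCalibration, SoilConfig, TemperatureResponseParams
from .imaging_geometry import top_coeff
from .thermal import TemperatureSeries, thermal_axis
from .water import WaterReleaseParams, water_content_from_potential

__all__ = [
    "QTL",
    "NoiseConfig",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_plants",
    "render_observations",
    "simulate_experiment",
    "write_experiment",
]

WELL_WATERED = "well_watered"
DROUGHT = "drought"

#: Generative area-to-trait polynomials (the structures the calibration
#: stage selects for): coefficient per term, no intercept.
TRUE_CALIBRATION = {
    "leaf_area": {"side": 1.6, "top": 0.4, "side2": 4.0e-6,
                  "top2": -3.0e-6, "side:top": 2.0e-6},
    "plant_weight": {"side": 9.0e-4, "side2": 4.0e-9, "side:top": 3.0e-9},
    "biomass": {"side": 1.45e-4, "top": 9.0e-5, "side2": 3.0e-10,
                "top2": 2.5e-10, "side:top": 2.0e-10},
}

TOP_EXPONENT = 0.9


@dataclass(frozen=True)
class QTL:
    """A planted additive QTL: the named latent parameter of every plant
    shifts by +effect for the Drysdale allele and -effect for Gladius."""

    marker: str
    parameter: str        # one of: size, K, t0, tr_coef
    effect: float
    phenology: bool = False


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise standard deviations (0 = noise-free rendering)."""

    pixel_rel: float = 0.02        # relative, on pixel areas
    cm_pix_sd: float = 10.0        # px, on the centre-of-mass coordinate
    pot_weight_sd: float = 2.0     # g, on logged pot weights
    calib_rel: float = 0.03        # relative, on harvested trait measurements
    calib_area_rel: float = 0.02   # relative, on harvest projected areas
    release_rel: float = 0.01      # relative (1% of theta), release curve

    def off(self) -> "NoiseConfig":
        return NoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_qtls() -> tuple[QTL, ...]:
    return (
        QTL("chr1_m10", "size", 0.04),
        QTL("chr2_m05", "K", 0.005),
        QTL("chr3_m12", "tr_coef", 0.03),
        QTL("chr5_m08", "t0", 1.5, phenology=True),
        QTL("chr7_m03", "t0", 1.2, phenology=True),
    )


@dataclass
class SimulationConfig:
    """All knobs of the virtual experiment; the defaults are the study
    conditions the simulator emulates."""

    seed: int
    n_lines: int = 150
    n_reps: int = 2
    treatments: dict = field(default_factory=lambda: {
        WELL_WATERED: -0.02, DROUGHT: -0.05})
    # genome
    n_chromosomes: int = 7
    markers_per_chromosome: int = 20
    chromosome_length_cM: float = 100.0
    missing_rate: float = 0.02
    qtls: tuple[QTL, ...] = field(default_factory=_default_qtls)
    # schedule (calendar days since sowing)
    start_day: float = 21.0
    end_day: float = 61.0
    cadence_d: float = 2.0
    n_artificial: int = 2
    # greenhouse temperature sinusoid, logged hourly
    temp_min_C: float = 17.0
    temp_max_C: float = 25.0
    temp_cadence_h: float = 1.0
    # latent growth population (well-watered base; drought multipliers below)
    K_base: dict = field(default_factory=lambda: {WELL_WATERED: 0.143, DROUGHT: 0.130})
    t0_base: dict = field(default_factory=lambda: {WELL_WATERED: 56.0, DROUGHT: 51.0})
    size_base: dict = field(default_factory=lambda: {WELL_WATERED: 1.0, DROUGHT: 0.32})
    side_max_mm2: float = 80_000.0   # final side area of an average WW plant
    top_ratio: float = 0.5           # top amplitude relative to side
    # genetic (line) and environmental (replicate) variation; the
    # replicate component dominates so broad-sense heritability spans the
    # low-to-moderate range typical of platform traits
    line_sd: dict = field(default_factory=lambda: {
        "K": 0.005, "t0": 1.5, "size": 0.07, "arch": 0.05, "tr_coef": 0.05})
    rep_sd: dict = field(default_factory=lambda: {
        "K": 0.014, "t0": 3.5, "size": 0.12, "arch": 0.06, "tr_coef": 0.10})
    # water use: transpiration = tr_coef * LA/(1 + LA/la_sat) * demand,
    # the saturation expressing self-shading of large canopies
    tr_coef: dict = field(default_factory=lambda: {
        WELL_WATERED: 5.3e-3, DROUGHT: 3.2e-3})  # g water per mm2 leaf per day
    la_sat_mm2: float = 60_000.0
    demand_amp: float = 0.10
    demand_period_d: float = 10.0
    evap_per_theta: float = 18.0     # g/day per unit gravimetric content
    theta_floor_margin: float = 0.03  # wilting guard above theta_r
    soil: SoilConfig = field(default_factory=SoilConfig)
    release: WaterReleaseParams = field(default_factory=lambda: WaterReleaseParams(
        theta_r=0.05, theta_s=0.45, a_vg=25.0, n_vg=2.0))
    n_release_pots: int = 5
    # calibration harvest design (parental genotypes, twice a week)
    harvest_days: tuple = tuple(float(d) for d in range(14, 61, 3))
    harvest_plants_per_cell: int = 3
    harvest_size_sd: float = 0.15
    # observation noise
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    camera: CameraCalibration = field(default_factory=CameraCalibration)
    thermal: TemperatureResponseParams = field(
        default_factory=lambda: TemperatureResponseParams(explicit=True))
    # truth reporting window (thermal days)
    window: tuple = (35.0, 50.0)

    @property
    def marker_names(self) -> list[str]:
        return [f"chr{c + 1}_m{m + 1:02d}"
                for c in range(self.n_chromosomes)
                for m in range(self.markers_per_chromosome)]


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator):
    """RIL genotypes (+1 Drysdale / -1 Gladius, NaN missing) and marker map.

    Markers are equally spaced along each chromosome; linkage follows the
    Haldane map function with the RIL (repeated-selfing) correction
    R = 2r/(1+2r), so adjacent-marker correlation decays with cM distance.
    """
    markers = cfg.marker_names
    M = cfg.markers_per_chromosome
    spacing = cfg.chromosome_length_cM / max(M - 1, 1)
    r = 0.5 * (1.0 - np.exp(-2.0 * spacing / 100.0))
    R = 2.0 * r / (1.0 + 2.0 * r)
    calls = np.empty((cfg.n_lines, len(markers)))
    for c in range(cfg.n_chromosomes):
        first = rng.choice([-1.0, 1.0], size=cfg.n_lines)
        chrom = [first]
        for _ in range(M - 1):
            flip = rng.random(cfg.n_lines) < R
            chrom.append(np.where(flip, -chrom[-1], chrom[-1]))
        calls[:, c * M:(c + 1) * M] = np.column_stack(chrom)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = np.nan
    lines = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    geno = pd.DataFrame(calls, index=pd.Index(lines, name="line_id"),
                        columns=markers)
    marker_map = pd.DataFrame({
        "marker": markers,
        "chromosome": [f"chr{c + 1}" for c in range(cfg.n_chromosomes)
                       for _ in range(M)],
        "cM": [m * spacing for _ in range(cfg.n_chromosomes) for m in range(M)],
    })
    return geno, marker_map


# ---------------------------------------------------------------------------
# latent plants and true traits


def _poly_eval(coeffs: dict, side, top):
    terms = {"side": side, "top": top, "side2": side ** 2,
             "top2": top ** 2, "side:top": side * top}
    out = 0.0
    for name, c in coeffs.items():
        out = out + c * terms[name]
    return out


def _qtl_shift(cfg: SimulationConfig, geno: pd.DataFrame, line_id: str,
               parameter: str) -> float:
    shift = 0.0
    for q in cfg.qtls:
        if q.parameter != parameter or q.marker not in geno.columns:
            continue
        g = geno.at[line_id, q.marker]
        if np.isfinite(g):
            shift += q.effect * g
    return shift


class PlantCurves:
    """True trait curves of one plant as functions of thermal time."""

    def __init__(self, K, t0, c1, c2):
        self.K, self.t0, self.c1, self.c2 = K, t0, c1, c2

    def latent(self, t):
        return 1.0 / (1.0 + np.exp(-self.K * (np.asarray(t, dtype=float) - self.t0)))

    def areas(self, t):
        S = self.latent(t)
        return self.c1 * S, self.c2 * S ** TOP_EXPONENT

    def trait(self, name, t):
        side, top = self.areas(t)
        return _poly_eval(TRUE_CALIBRATION[name], side, top)


def simulate_plants(cfg: SimulationConfig, geno: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-plant latent parameters: population base + treatment
    effect + line effect + QTL shifts + replicate residual.

    Returns one row per plant with the latent parameters and plant/pot
    identifiers.  Parameter draws that would give a non-positive final
    size are redrawn.
    """
    lines = list(geno.index)
    line_eff = {
        p: dict(zip(lines, rng.normal(0.0, cfg.line_sd[p], size=len(lines))))
        for p in ("K", "t0", "size", "arch", "tr_coef")
    }
    rows = []
    for line in lines:
        for rep in range(1, cfg.n_reps + 1):
            for trt in cfg.treatments:
                for _attempt in range(20):
                    size = (cfg.size_base[trt]
                            * (1.0 + line_eff["size"][line]
                               + _qtl_shift(cfg, geno, line, "size")
                               + rng.normal(0.0, cfg.rep_sd["size"])))
                    if size > 0.05:
                        break
                K = (cfg.K_base[trt] + line_eff["K"][line]
                     + _qtl_shift(cfg, geno, line, "K")
                     + rng.normal(0.0, cfg.rep_sd["K"]))
                K = max(K, 0.05)
                t0 = (cfg.t0_base[trt] + line_eff["t0"][line]
                      + _qtl_shift(cfg, geno, line, "t0")
                      + rng.normal(0.0, cfg.rep_sd["t0"]))
                arch = (1.0 + line_eff["arch"][line]
                        + rng.normal(0.0, cfg.rep_sd["arch"]))
                tr = (cfg.tr_coef[trt]
                      * (1.0 + line_eff["tr_coef"][line]
                         + _qtl_shift(cfg, geno, line, "tr_coef")
                         + rng.normal(0.0, cfg.rep_sd["tr_coef"])))
                c1 = cfg.side_max_mm2 * size
                c2 = cfg.side_max_mm2 * cfg.top_ratio * size * arch
                rows.append({
                    "plant_id": f"{line}_r{rep}_{'ww' if trt == WELL_WATERED else 'd'}",
                    "line_id": line, "replicate": rep, "treatment": trt,
                    "K": K, "t0": t0, "size": size, "arch": arch,
                    "c1": c1, "c2": c2, "tr_coef": tr,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# schedules and environment


def temperature_log(cfg: SimulationConfig) -> pd.DataFrame:
    """Hourly greenhouse log: sinusoid with night minimum and day maximum."""
    hours = np.arange(0.0, (cfg.end_day + 1) * 24.0 + 1e-9, cfg.temp_cadence_h)
    mid = 0.5 * (cfg.temp_min_C + cfg.temp_max_C)
    amp = 0.5 * (cfg.temp_max_C - cfg.temp_min_C)
    temps = mid + amp * np.sin(2.0 * np.pi * (hours - 8.0) / 24.0)
    return pd.DataFrame({"timestamp_h": hours, "temp_C": temps})


def _schedule(cfg: SimulationConfig) -> np.ndarray:
    return np.arange(cfg.start_day, cfg.end_day + 1e-9, cfg.cadence_d)


def _demand(cfg: SimulationConfig, day: float) -> float:
    return 1.0 + cfg.demand_amp * np.sin(2.0 * np.pi * day / cfg.demand_period_d)


def _interval_transpiration(cfg: SimulationConfig, plant, tt_of_day,
                            days: np.ndarray) -> np.ndarray:
    """True transpiration (g) of one plant over each watering interval.

    Demand is constant within an interval (it varies between intervals),
    leaf area is taken at the interval midpoint, and self-shading
    saturates the effective transpiring area.  Transpiration is capped so
    the pot never dries below theta_r + margin (stomatal closure)."""
    curves = PlantCurves(plant.K, plant.t0, plant.c1, plant.c2)
    la_mid = np.atleast_1d(
        curves.trait("leaf_area", tt_of_day(0.5 * (days[:-1] + days[1:]))))
    eff = la_mid / (1.0 + la_mid / cfg.la_sat_mm2)
    transp = np.array([
        plant.tr_coef * e * _demand(cfg, d) * (d2 - d)
        for e, d, d2 in zip(eff, days[:-1], days[1:])
    ])
    theta_target = water_content_from_potential(
        cfg.treatments[plant.treatment], cfg.release)
    evap = cfg.evap_per_theta * theta_target * cfg.cadence_d
    max_loss = (theta_target - cfg.release.theta_r
                - cfg.theta_floor_margin) * cfg.soil.dry_soil_g
    return np.minimum(transp, max(max_loss - evap, 0.0))


# ---------------------------------------------------------------------------
# rendering observations


def _render_images(cfg, plants, tt_of_day, rng) -> pd.DataFrame:
    days = _schedule(cfg)
    tts = tt_of_day(days)
    rows = []
    for p in plants.itertuples():
        curves = PlantCurves(p.K, p.t0, p.c1, p.c2)
        side_mm2, top_mm2 = curves.areas(tts)
        height_factor = p.size ** 0.25
        cm = np.clip(1900.0 - 700.0 * height_factor * curves.latent(tts) ** 0.6,
                     200.0, None)
        cm = cm + rng.normal(0.0, cfg.noise.cm_pix_sd, size=cm.size)
        cm = np.clip(cm, 0.0, None)
        tc = np.asarray(top_coeff(cm, cfg.camera))
        side_px = side_mm2 / cfg.camera.side_coeff ** 2
        top_px = top_mm2 / tc ** 2
        if cfg.noise.pixel_rel > 0:
            side_px = side_px * (1.0 + rng.normal(0.0, cfg.noise.pixel_rel, side_px.size))
            top_px = top_px * (1.0 + rng.normal(0.0, cfg.noise.pixel_rel, top_px.size))
        for d, s, t, c in zip(days, np.clip(side_px, 0, None),
                              np.clip(top_px, 0, None), cm):
            rows.append((p.plant_id, d, s, t, c))
    return pd.DataFrame(rows, columns=["plant_id", "day", "side_area_px",
                                       "top_area_px", "cm_pix"])


def _render_pot_logs(cfg, plants, tt_of_day, rng) -> pd.DataFrame:
    """Weighing/watering log.  Discrete water balance per interval: every
    weighing rewaters the pot to its treatment's target water content (from
    the true release curve), evaporation over an interval depends on the
    post-watering content, transpiration on leaf area x demand."""
    days = _schedule(cfg)
    tts = tt_of_day(days)
    theta_target = {trt: water_content_from_potential(psi, cfg.release)
                    for trt, psi in cfg.treatments.items()}
    rows = []

    def pot_rows(pid, trt, transp_per_interval, pw_vals, artificial):
        theta_t = theta_target[trt]
        evap = cfg.evap_per_theta * theta_t * cfg.cadence_d
        stored = theta_t * cfg.soil.dry_soil_g
        for i, d in enumerate(days):
            loss = 0.0 if i == 0 else evap + transp_per_interval[i - 1]
            now = stored - loss
            true_before = cfg.soil.tare_g + cfg.soil.dry_soil_g + now + pw_vals[i]
            water_added = stored - now
            eps = rng.normal(0.0, cfg.noise.pot_weight_sd) if cfg.noise.pot_weight_sd > 0 else 0.0
            wb = true_before + eps
            rows.append((pid, trt, float(d), wb, wb + water_added,
                         water_added, artificial))

    for p in plants.itertuples():
        curves = PlantCurves(p.K, p.t0, p.c1, p.c2)
        transp = _interval_transpiration(cfg, p, tt_of_day, days)
        pw_vals = np.atleast_1d(curves.trait("plant_weight", tts))
        pot_rows(p.plant_id, p.treatment, transp, pw_vals, False)

    zeros = np.zeros(days.size - 1)
    for trt in cfg.treatments:
        for j in range(1, cfg.n_artificial + 1):
            pid = f"art_{'ww' if trt == WELL_WATERED else 'd'}_{j}"
            pot_rows(pid, trt, zeros, np.zeros(days.size), True)

    return pd.DataFrame(rows, columns=["plant_id", "treatment", "time_d",
                                       "weight_before_g", "weight_after_g",
                                       "water_added_g", "is_artificial"])


def _render_calibration(cfg, rng) -> pd.DataFrame:
    """Destructive harvest of the two parental genotypes: projected areas
    plus measured fresh weight, dry biomass and planimeter leaf area."""
    rows = []
    temp = temperature_log(cfg)
    series = TemperatureSeries.from_frame(temp)
    all_days = np.asarray(cfg.harvest_days, dtype=float)
    tt_days = thermal_axis(series, cfg.thermal, all_days)
    for gi, genotype in enumerate(("Drysdale", "Gladius")):
        g_size = 1.0 + (0.05 if gi == 0 else -0.05)
        for trt in cfg.treatments:
            for d, tt in zip(all_days, tt_days):
                for k in range(cfg.harvest_plants_per_cell):
                    size = (cfg.size_base[trt] * g_size
                            * (1.0 + rng.normal(0.0, cfg.harvest_size_sd)))
                    size = max(size, 0.05)
                    arch = 1.0 + rng.normal(0.0, cfg.line_sd["arch"])
                    K = cfg.K_base[trt] + rng.normal(0.0, cfg.rep_sd["K"])
                    t0 = cfg.t0_base[trt] + rng.normal(0.0, cfg.rep_sd["t0"])
                    curves = PlantCurves(K, t0, cfg.side_max_mm2 * size,
                                         cfg.side_max_mm2 * cfg.top_ratio * size * arch)
                    side, top = curves.areas(tt)
                    if cfg.noise.calib_area_rel > 0:
                        side = side * (1.0 + rng.normal(0.0, cfg.noise.calib_area_rel))
                        top = top * (1.0 + rng.normal(0.0, cfg.noise.calib_area_rel))
                    vals = {}
                    for trait in TRUE_CALIBRATION:
                        v = _poly_eval(TRUE_CALIBRATION[trait], side, top)
                        if cfg.noise.calib_rel > 0:
                            v = v * (1.0 + rng.normal(0.0, cfg.noise.calib_rel))
                        vals[trait] = max(v, 1e-6)
                    rows.append({
                        "genotype_id": genotype, "treatment": trt, "day": d,
                        "side_area": max(side, 0.0), "top_area": max(top, 0.0),
                        **vals,
                    })
    return pd.DataFrame(rows)


def _render_release(cfg, rng) -> pd.DataFrame:
    """Pressure-chamber observations from the drying pots: each of the
    replicate pots is sampled from retention capacity down to -1.6 MPa."""
    psi1 = -np.geomspace(0.01, 1.6, 15)
    psi = np.tile(psi1, cfg.n_release_pots)
    theta = water_content_from_potential(psi, cfg.release)
    if cfg.noise.release_rel > 0:
        theta = theta * (1.0 + rng.normal(0.0, cfg.noise.release_rel, theta.size))
    pot = np.repeat(np.arange(1, cfg.n_release_pots + 1), psi1.size)
    return pd.DataFrame({"pot": pot, "theta": theta, "psi_MPa": psi})


# ---------------------------------------------------------------------------
# ground truth


def _truth_traits(cfg, plants, tt_of_day) -> pd.DataFrame:
    """Per-plant true derived traits, computed from the true curves with
    the same window conventions the pipeline documents (thermal window,
    pro-rata attribution of watering intervals)."""
    a, b = cfg.window
    days = _schedule(cfg)
    tts = np.asarray(tt_of_day(days))
    grid = np.arange(a, b + 1e-9, 0.1)
    rows = []
    for p in plants.itertuples():
        curves = PlantCurves(p.K, p.t0, p.c1, p.c2)
        B = lambda t: curves.trait("biomass", t)
        LA = lambda t: curves.trait("leaf_area", t)
        growth_ave = (B(b) - B(a)) / (b - a)
        ler_ave = (LA(b) - LA(a)) / (b - a)
        h = 1e-5
        rgr = np.trapezoid(
            (B(grid + h) - B(grid - h)) / (2 * h) / B(grid), grid) / (b - a)
        rer = np.trapezoid(
            (LA(grid + h) - LA(grid - h)) / (2 * h) / LA(grid), grid) / (b - a)
        total = 0.0
        transp_intervals = _interval_transpiration(cfg, p, tt_of_day, days)
        for i in range(days.size - 1):
            u, w = tts[i], tts[i + 1]
            if w <= a or u >= b:
                continue
            frac = (min(w, b) - max(u, a)) / (w - u)
            total += transp_intervals[i] * frac
        tr = total / (b - a)
        mean_la = float(np.trapezoid(LA(grid), grid) / (b - a))
        rows.append({
            "plant_id": p.plant_id, "line_id": p.line_id,
            "replicate": p.replicate, "treatment": p.treatment,
            "K": p.K, "t0": p.t0,
            "V_final_biomass": _poly_eval(TRUE_CALIBRATION["biomass"], p.c1,
                                          p.c2),
            "V_final_leaf_area": _poly_eval(TRUE_CALIBRATION["leaf_area"], p.c1,
                                            p.c2),
            "V_final_plant_weight": _poly_eval(TRUE_CALIBRATION["plant_weight"],
                                               p.c1, p.c2),
            "Growth_AVE": growth_ave, "LER_AVE": ler_ave,
            "RGR": rgr, "RER": rer,
            "TR": tr, "TR_area": tr / mean_la,
            "WUE": (B(b) - B(a)) / total if total > 0 else np.nan,
            "total_transpiration_g": total,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level API


def simulate_experiment(cfg: SimulationConfig) -> dict:
    """Run the full virtual experiment.

    Returns a dict of DataFrames: observation streams under plain keys
    (``images``, ``pot_logs``, ``temperature``, ``calibration``,
    ``water_release``, ``genotypes``, ``marker_map``) and ground truth
    under ``truth/*`` keys the pipeline never reads.
    """
    rng = np.random.default_rng(cfg.seed)
    geno, marker_map = simulate_genotypes(cfg, rng)
    plants = simulate_plants(cfg, geno, rng)
    temp = temperature_log(cfg)
    series = TemperatureSeries.from_frame(temp)

    day_grid = np.arange(0.0, cfg.end_day + 1.0 + 1e-9, 0.25)
    tt_grid = thermal_axis(series, cfg.thermal, day_grid)

    def tt_of_day(d):
        return np.interp(np.asarray(d, dtype=float), day_grid, tt_grid)

    images = _render_images(cfg, plants, tt_of_day, rng)
    pot_logs = _render_pot_logs(cfg, plants, tt_of_day, rng)
    calibration = _render_calibration(cfg, rng)
    release_obs = _render_release(cfg, rng)
    truth = _truth_traits(cfg, plants, tt_of_day)

    geno_out = geno.reset_index().melt(
        id_vars="line_id", var_name="marker", value_name="call")
    geno_out["call"] = geno_out["call"].map({1.0: "A", -1.0: "B"})

    return {
        "images": images,
        "pot_logs": pot_logs,
        "temperature": temp,
        "calibration": calibration,
        "water_release": release_obs,
        "genotypes": geno_out,
        "marker_map": marker_map,
        "truth/plants": plants,
        "truth/traits": truth,
        "truth/qtls": pd.DataFrame([asdict(q) for q in cfg.qtls]),
        "truth/release_params": pd.DataFrame([asdict(cfg.release)]),
    }


def write_experiment(cfg: SimulationConfig, out_dir) -> None:
    """Write all observation CSVs plus truth files and a manifest."""
    import hashlib
    from pathlib import Path

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    data = simulate_experiment(cfg)
    checksums = {}
    for key, df in data.items():
        path = out / f"{key}.csv"
        df.to_csv(path, index=False)
        checksums[key] = hashlib.sha256(path.read_bytes()).hexdigest()
    cfg_repr = {k: repr(v) for k, v in asdict(cfg).items()}
    manifest = {
        "seed": cfg.seed,
        "config": cfg_repr,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_repr, sort_keys=True).encode()).hexdigest(),
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
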