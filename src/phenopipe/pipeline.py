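"""End-to-end orchestration: pixels to genetics-ready traits.

Stage order: imaging geometry -> area-to-trait calibration -> thermal
axis -> per-plant growth fits -> water balance and transpiration ->
derived trait table -> heritability and marker scan.  A failure for one
plant (e.g. a non-converged fit) is recorded and never aborts the run.
All intermediate products are plain DataFrames / CSV with documented
columns; the run manifest records config hash, seed and output checksums
so that reruns are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import genetics, growth, water
from .config import PipelineConfig
from .imaging_geometry import convert_image_table
from .thermal import TemperatureSeries, thermal_axis

logger = logging.getLogger(__name__)

#: Trait columns of the derived table, in report order.
TRAIT_COLUMNS = ["Growth_AVE", "RGR", "Tx_growth", "K_RGR",
                 "LER_AVE", "RER", "K_RER", "Tx_LER",
                 "TR", "TR_area", "WUE"]


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    images_mm2: pd.DataFrame
    calibration_models: dict
    trait_series: pd.DataFrame
    fits: dict                      # (plant_id, trait) -> GrowthFit
    fits_table: pd.DataFrame
    water_balance: pd.DataFrame
    traits: pd.DataFrame            # one row per plant
    relative_responses: pd.DataFrame
    summary: pd.DataFrame           # per trait x treatment stats + h2
    scans: dict                     # trait -> ScanResult
    release_params: water.WaterReleaseParams
    qc: dict
    failures: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual stages


def stage_geometry(images: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    return convert_image_table(images, cfg.camera)


def stage_calibration(calib: pd.DataFrame, cfg: PipelineConfig) -> dict:
    return cal.calibrate_all(calib, per_treatment=cfg.per_treatment_calibration)


def stage_thermal(temperature: pd.DataFrame, cfg: PipelineConfig):
    """Return tt_of_day, a vectorised calendar-day -> thermal-day map."""
    series = TemperatureSeries.from_frame(temperature)
    day_grid = np.arange(series.timestamps_h[0] / 24.0,
                         series.timestamps_h[-1] / 24.0 + 1e-9, 0.25)
    tt_grid = thermal_axis(series, cfg.thermal, day_grid)

    def tt_of_day(d):
        out = np.interp(np.asarray(d, dtype=float), day_grid, tt_grid)
        return float(out) if np.ndim(d) == 0 else out

    return tt_of_day


def stage_trait_series(images_mm2: pd.DataFrame, models: dict,
                       tt_of_day, cfg: PipelineConfig) -> pd.DataFrame:
    """Calibrated trait values per plant per imaging day, on the thermal
    axis.  Negative predictions (possible early in growth) are kept raw
    and flagged in the ``issues`` column."""
    out = images_mm2.copy()
    out["t20"] = tt_of_day(out["day"].to_numpy())
    issues = np.full(len(out), "", dtype=object)
    for trait in cal.TRAITS:
        model = models[trait]
        pred = cal.predict_trait(model, out["side_area_mm2"].to_numpy(),
                                 out["top_area_mm2"].to_numpy())
        out[trait] = pred
        neg = np.asarray(pred) < 0
        issues[neg] = np.char.add(issues[neg].astype(str), f"neg_{trait};")
    out["issues"] = issues
    return out


def stage_growth(trait_series: pd.DataFrame, cfg: PipelineConfig,
                 failures: list) -> tuple[dict, pd.DataFrame]:
    """Per-plant, per-trait growth-model selection."""
    fits: dict = {}
    rows = []
    for pid, grp in trait_series.groupby("plant_id", sort=True):
        g = grp.sort_values("t20")
        t = g["t20"].to_numpy()
        for trait in cal.TRAITS:
            fit = growth.select_growth_model(
                t, g[trait].to_numpy(), candidates=cfg.growth_candidates)
            if fit is None:
                failures.append((pid, trait, "no growth model converged"))
                continue
            fits[(pid, trait)] = fit
            rows.append({"plant_id": pid, "trait": trait,
                         "model_kind": fit.model_kind, **fit.params,
                         "rss": fit.rss, "bic": fit.bic,
                         "converged": fit.converged})
    return fits, pd.DataFrame(rows)


def _plant_weight_fn(fits: dict, trait_series: pd.DataFrame, tt_of_day,
                     mode: str = "population_mean"):
    """Modelled fresh plant weight used to correct pot weights.

    ``population_mean`` (the default): the mean modelled weight of all
    plants in the treatment at that time; ``per_plant``: each plant's own
    modelled weight."""
    plant_trt = (trait_series[["plant_id", "treatment"]]
                 .drop_duplicates().set_index("plant_id")["treatment"]
                 if "treatment" in trait_series.columns else None)

    by_trt: dict[str, list] = {}
    for (pid, trait), fit in fits.items():
        if trait != "plant_weight" or not fit.converged:
            continue
        trt = plant_trt.get(pid) if plant_trt is not None else None
        by_trt.setdefault(trt, []).append(fit)
    cache: dict = {}

    def pw(plant_id, treatment, day):
        if mode == "per_plant":
            fit = fits.get((plant_id, "plant_weight"))
            if fit is not None and fit.converged:
                return float(growth.predict(fit, tt_of_day(day)))
        key = (treatment, round(float(day), 6))
        if key not in cache:
            group = by_trt.get(treatment) or [f for fl in by_trt.values() for f in fl]
            t20 = tt_of_day(day)
            cache[key] = float(np.mean([growth.predict(f, t20) for f in group]))
        return cache[key]

    return pw


def stage_water(pot_logs: pd.DataFrame, release_obs: pd.DataFrame,
                fits: dict, trait_series: pd.DataFrame, tt_of_day,
                cfg: PipelineConfig):
    release = water.fit_water_release(release_obs["theta"].to_numpy(),
                                      release_obs["psi_MPa"].to_numpy())
    pw_fn = _plant_weight_fn(fits, trait_series, tt_of_day,
                             mode=cfg.plant_weight_correction)
    balance = water.water_balance(pot_logs, release, cfg.soil.tare_g,
                                  cfg.soil.dry_soil_g, pw_fn)
    return release, balance


def stage_traits_table(fits: dict, balance: pd.DataFrame, tt_of_day,
                       meta: pd.DataFrame, cfg: PipelineConfig,
                       failures: list) -> pd.DataFrame:
    """One row per plant: the derived trait set (Table-style naming)."""
    window = (cfg.window.start, cfg.window.end)
    rows = []
    for rec in meta.itertuples():
        pid = rec.plant_id
        row = {"plant_id": pid, "line_id": rec.line_id,
               "replicate": rec.replicate, "treatment": rec.treatment}
        bfit = fits.get((pid, "biomass"))
        lfit = fits.get((pid, "leaf_area"))
        try:
            if bfit is not None and bfit.converged:
                g_ave, rgr, flag = growth.window_averages(
                    bfit, window, rgr_mode=cfg.rgr_mode)
                row.update(Growth_AVE=g_ave, RGR=rgr, window_flagged=flag)
                if bfit.model_kind == "logistic3":
                    row.update(Tx_growth=bfit.params["t0"],
                               K_RGR=bfit.params["K"])
            if lfit is not None and lfit.converged:
                l_ave, rer, _ = growth.window_averages(
                    lfit, window, rgr_mode=cfg.rgr_mode)
                row.update(LER_AVE=l_ave, RER=rer)
                if lfit.model_kind == "logistic3":
                    row.update(Tx_LER=lfit.params["t0"],
                               K_RER=lfit.params["K"])
            sub = balance[balance["plant_id"] == pid]
            if len(sub) and bfit is not None and lfit is not None \
                    and bfit.converged and lfit.converged:
                wt = water.transpiration_traits(sub, tt_of_day, bfit, lfit,
                                                window)
                row.update(TR=wt["TR"], TR_area=wt["TR_area"],
                           TR_cal=wt["TR_cal"], WUE=wt["WUE"],
                           psi_mean=wt["psi_mean"],
                           total_transpiration_g=wt["total_transpiration_g"])
        except (ValueError, KeyError) as exc:
            failures.append((pid, "traits", str(exc)))
        rows.append(row)
    return pd.DataFrame(rows)


def stage_relative_responses(traits: pd.DataFrame) -> pd.DataFrame:
    """Pair the two treatments of each line x replicate (grown next to
    each other) and compute the per-MPa relative response of each trait."""
    trts = sorted(traits["treatment"].unique())
    if len(trts) != 2:
        return pd.DataFrame()
    d_name = "drought" if "drought" in trts else trts[0]
    w_name = [t for t in trts if t != d_name][0]
    ww = traits[traits["treatment"] == w_name].set_index(["line_id", "replicate"])
    dr = traits[traits["treatment"] == d_name].set_index(["line_id", "replicate"])
    shared = ww.index.intersection(dr.index)
    rows = []
    for key in shared:
        a, b = ww.loc[key], dr.loc[key]
        if pd.isna(a.get("psi_mean")) or pd.isna(b.get("psi_mean")):
            continue
        row = {"line_id": key[0], "replicate": key[1]}
        for col in TRAIT_COLUMNS:
            if col in a and col in b and pd.notna(a[col]) and pd.notna(b[col]):
                resp, undef = water.relative_response(
                    a[col], b[col], a["psi_mean"], b["psi_mean"])
                row[f"resp_{col}"] = resp
                row[f"resp_{col}_undefined"] = undef
        rows.append(row)
    return pd.DataFrame(rows)


def stage_summary(traits: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Per trait x treatment descriptive stats, heritability and the
    line-effect ANOVA P (the descriptive-table layout of the report)."""
    rows = []
    for trt, grp in traits.groupby("treatment"):
        n_rep = int(grp.groupby("line_id").size().max())
        for col in TRAIT_COLUMNS:
            if col not in grp.columns:
                continue
            vals = grp[["line_id", col]].rename(columns={col: "value"}).dropna()
            if vals.empty:
                continue
            entry = {
                "treatment": trt, "trait": col,
                "mean": vals["value"].mean(), "sd": vals["value"].std(ddof=1),
                "min": vals["value"].min(), "max": vals["value"].max(),
                "n": len(vals),
            }
            try:
                s2g, s2e = genetics.variance_components(vals)
                entry["h2"] = genetics.heritability(s2g, s2e, n_rep)
                entry["anova_p"] = genetics.line_anova_pvalue(vals)
            except ValueError:
                entry["h2"] = np.nan
                entry["anova_p"] = np.nan
            rows.append(entry)
    return pd.DataFrame(rows)


def _pivot_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Melted (line_id, marker, call A/B/NaN) -> numeric line x marker."""
    wide = genotypes.pivot(index="line_id", columns="marker", values="call")
    return wide.apply(lambda c: c.map({"A": 1.0, "B": -1.0})).astype(float)


def stage_genetics(traits: pd.DataFrame, genotypes: pd.DataFrame,
                   marker_map: pd.DataFrame, cfg: PipelineConfig,
                   scan_traits=("Growth_AVE", "LER_AVE", "TR", "WUE"),
                   covariate_markers: tuple = (), seed: int = 0) -> dict:
    """Single-marker scan per treatment for the requested traits, each
    with its own permutation threshold."""
    G = _pivot_genotypes(genotypes)
    covariates = None
    if covariate_markers:
        covariates = G[list(covariate_markers)].copy()
        # mean-impute so covariate missingness does not drop lines
        covariates = covariates.fillna(covariates.mean())
        G = G.drop(columns=list(covariate_markers))
    scans = {}
    for trt, grp in traits.groupby("treatment"):
        for trait in scan_traits:
            if trait not in grp.columns:
                continue
            line_means = grp.groupby("line_id")[trait].mean().dropna()
            if len(line_means) < 50:
                logger.warning("skipping scan %s/%s: only %d lines",
                               trt, trait, len(line_means))
                continue
            scans[f"{trait}/{trt}"] = genetics.single_marker_scan(
                line_means, G, marker_map=marker_map, covariates=covariates,
                n_permutations=cfg.n_permutations, alpha=cfg.alpha, seed=seed)
    return scans


# ---------------------------------------------------------------------------
# full run


def run_pipeline(data: dict, cfg: PipelineConfig | None = None,
                 scan_traits=("Growth_AVE", "LER_AVE", "TR", "WUE"),
                 covariate_markers: tuple = (), seed: int = 0,
                 run_genetics: bool = True) -> PipelineResult:
    """Execute all stages on a dataset dict (keys: images, pot_logs,
    temperature, calibration, water_release, genotypes, marker_map).

    Ground-truth tables (``truth/*`` keys) are ignored by construction.
    """
    cfg = cfg or PipelineConfig()
    failures: list = []

    images_mm2 = stage_geometry(data["images"], cfg)
    models = stage_calibration(data["calibration"], cfg)
    tt_of_day = stage_thermal(data["temperature"], cfg)

    # attach treatment/line metadata from the pot logs
    meta_cols = data["pot_logs"][~data["pot_logs"]["is_artificial"]][
        ["plant_id", "treatment"]].drop_duplicates()
    series = stage_trait_series(images_mm2, models, tt_of_day, cfg)
    series = series.merge(meta_cols, on="plant_id", how="left")

    fits, fits_table = stage_growth(series, cfg, failures)
    release, balance = stage_water(data["pot_logs"], data["water_release"],
                                   fits, series, tt_of_day, cfg)

    meta = meta_cols.copy()
    parts = meta["plant_id"].str.extract(r"^(?P<line_id>[^_]+)_r(?P<replicate>\d+)")
    meta["line_id"] = parts["line_id"]
    meta["replicate"] = parts["replicate"].astype(float).fillna(1).astype(int)
    traits = stage_traits_table(fits, balance, tt_of_day, meta, cfg, failures)
    responses = stage_relative_responses(traits)
    summary = stage_summary(traits, cfg)

    scans = {}
    if run_genetics and "genotypes" in data and len(traits):
        scans = stage_genetics(traits, data["genotypes"], data.get("marker_map"),
                               cfg, scan_traits=scan_traits,
                               covariate_markers=covariate_markers, seed=seed)

    qc = {
        "n_plants": int(meta["plant_id"].nunique()),
        "n_failures": len(failures),
        "n_nonconverged_fits": int((~fits_table["converged"]).sum())
        if len(fits_table) else 0,
        "n_negative_predictions": int((series["issues"] != "").sum()),
        "n_floored_transpiration": int(balance["floored"].sum()),
        "n_clamped_theta": int(balance["theta_clamped"].sum()),
        "n_carried_evaporation": int(balance["evap_carried"].sum()),
        "n_skipped_markers": int(sum(
            s.table["skipped_monomorphic"].sum() for s in scans.values()))
        if scans else 0,
    }

    return PipelineResult(
        images_mm2=images_mm2, calibration_models=models, trait_series=series,
        fits=fits, fits_table=fits_table, water_balance=balance,
        traits=traits, relative_responses=responses, summary=summary,
        scans=scans, release_params=release, qc=qc, failures=failures,
    )


def load_experiment(in_dir) -> dict:
    """Read the observation CSVs of a simulated/real experiment directory.
    ``truth/`` files are deliberately not loaded."""
    p = Path(in_dir)
    data = {}
    for key in ("images", "pot_logs", "temperature", "calibration",
                "water_release", "genotypes", "marker_map"):
        f = p / f"{key}.csv"
        if f.exists():
            data[key] = pd.read_csv(f)
    if "pot_logs" in data:
        data["pot_logs"]["is_artificial"] = data["pot_logs"][
            "is_artificial"].astype(bool)
    return data


def qc_report(result: PipelineResult) -> str:
    """Human-readable run report: QC flag counts and the per-treatment
    descriptive statistics (mean +/- SD, min-max, h2, ANOVA P)."""
    lines = ["Pipeline QC report", "=" * 40]
    for k, v in result.qc.items():
        lines.append(f"{k:32s} {v}")
    lines.append("")
    for trt, grp in result.summary.groupby("treatment"):
        lines.append(f"--- {trt} ---")
        lines.append(f"{'trait':12s} {'mean±SD':>22s} {'(min–max)':>24s} "
                     f"{'h2%':>7s} {'P':>9s}")
        for r in grp.itertuples():
            lines.append(
                f"{r.trait:12s} {r.mean:12.4g} ± {r.sd:-8.3g} "
                f"({r.min:9.4g}–{r.max:9.4g}) {r.h2:7.1f} {r.anova_p:9.2g}")
    if result.scans:
        lines.append("")
        lines.append("Marker scans (threshold at alpha, hits):")
        for name, s in result.scans.items():
            lines.append(f"  {name:24s} F*={s.threshold:6.2f} "
                         f"hits={len(s.hits)}")
    return "\n".join(lines)


def write_outputs(result: PipelineResult, out_dir) -> dict:
    """Write all result tables and the run manifest; returns checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "trait_series": result.trait_series,
        "fits": result.fits_table,
        "water_balance": result.water_balance,
        "traits": result.traits,
        "relative_responses": result.relative_responses,
        "summary": result.summary,
    }
    checksums = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    for name, scan in result.scans.items():
        path = out / f"scan_{name.replace('/', '_')}.csv"
        scan.table.to_csv(path, index=False)
        checksums[path.stem] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "calibration_models.json", "w") as fh:
        json.dump({k: m.to_dict() for k, m in result.calibration_models.items()},
                  fh, indent=2)
    with open(out / "qc_report.txt", "w") as fh:
        fh.write(qc_report(result))
    manifest = {"checksums": checksums, "qc": result.qc,
                "failures": result.failures}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return checksums
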