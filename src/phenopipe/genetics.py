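"""Population genetics statistics on the derived trait table.

Covers the downstream analyses run on the recombinant-inbred-line (RIL)
trait table: one-way random-effects variance components and broad-sense
heritability per treatment, a single-marker genome scan (trait ~
covariates + marker, F statistic per marker) with a genome-wide
permutation threshold from the max-over-markers null distribution, and
bootstrap mean growth curves per allele group.

Genotypes are biallelic RIL calls coded +1 for the Drysdale (parent A)
allele and -1 for Gladius (parent B); a positive additive effect means
the Drysdale allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "variance_components",
    "heritability",
    "line_anova_pvalue",
    "ScanResult",
    "single_marker_scan",
    "permutation_threshold",
    "allele_group_bootstrap",
]


def variance_components(values: pd.DataFrame, line_col: str = "line_id",
                        value_col: str = "value") -> tuple[float, float]:
    """Method-of-moments genetic and residual variance from replicated lines.

    One-way random-effects ANOVA on one treatment: sigma2_e is the
    within-line mean square; sigma2_G is (MS_between - MS_within)/n0 with
    n0 the effective replicate number for unbalanced data, floored at 0.
    """
    df = values[[line_col, value_col]].dropna()
    groups = df.groupby(line_col)[value_col]
    sizes = groups.size().to_numpy(dtype=float)
    if not np.any(sizes >= 2):
        raise ValueError("variance components need >= 2 replicates for some lines")
    a = sizes.size
    N = sizes.sum()
    grand = df[value_col].mean()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(((df[value_col] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(sizes ** 2) / N) / (a - 1)
    sigma2_e = ms_within
    sigma2_G = max((ms_between - ms_within) / n0, 0.0)
    return sigma2_G, sigma2_e


def heritability(sigma2_G: float, sigma2_e: float, r: int) -> float:
    """Broad-sense heritability on a line-mean basis, in percent:
    100 * sigma2_G / (sigma2_G + sigma2_e / r)."""
    if sigma2_G < 0 or sigma2_e < 0 or r < 1:
        raise ValueError("variances must be >= 0 and r >= 1")
    denom = sigma2_G + sigma2_e / r
    if denom == 0:
        return float("nan")  # undefined: no variance at all
    return 100.0 * sigma2_G / denom


def line_anova_pvalue(values: pd.DataFrame, line_col: str = "line_id",
                      value_col: str = "value") -> float:
    """P-value of the line effect in a one-way ANOVA (genetic variation test)."""
    groups = [g.to_numpy() for _, g in values.dropna().groupby(line_col)[value_col]]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two lines")
    _, p = stats.f_oneway(*groups)
    return float(p)


# ---------------------------------------------------------------------------
# single-marker scan


@dataclass
class ScanResult:
    """Genome-scan output: per-marker table, threshold and hits."""

    table: pd.DataFrame       # marker, chrom, cM, F, p, effect, above_threshold
    threshold: float
    alpha: float
    n_permutations: int

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["above_threshold"]]


def _residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residuals of y after OLS on [1, C] (column-wise if y is 2-D)."""
    n = y.shape[0]
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _prepare(traits: pd.Series, genotypes: pd.DataFrame,
             covariates: pd.DataFrame | None):
    lines = traits.dropna().index.intersection(genotypes.index)
    if covariates is not None:
        lines = lines.intersection(covariates.dropna().index)
    y = traits.loc[lines].to_numpy(dtype=float)
    G = genotypes.loc[lines].to_numpy(dtype=float)
    C = covariates.loc[lines].to_numpy(dtype=float) if covariates is not None else None
    return lines, y, G, C


def _marker_F(y: np.ndarray, G: np.ndarray, C: np.ndarray | None):
    """F statistic of each marker in trait ~ 1 + C + marker.

    Missing genotype calls are mean-imputed per marker; monomorphic
    markers get F = NaN.  Returns (F, df2, polymorphic mask).
    """
    n, M = G.shape
    X = G.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    poly = np.nanstd(X, axis=0) > 0
    q = 0 if C is None else C.shape[1]
    df2 = n - q - 2
    yr = _residualize(y.reshape(-1, 1), C)[:, 0]
    Xr = _residualize(X, C)
    ynorm = np.linalg.norm(yr)
    xnorm = np.linalg.norm(Xr, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xr.T @ yr) / (xnorm * ynorm)
        r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-12)
        F = r2 * df2 / (1.0 - r2)
    F[~poly | (xnorm == 0)] = np.nan
    return F, df2, poly


def single_marker_scan(traits: pd.Series, genotypes: pd.DataFrame,
                       marker_map: pd.DataFrame | None = None,
                       covariates: pd.DataFrame | None = None,
                       threshold: float | None = None,
                       n_permutations: int = 1000, alpha: float = 0.05,
                       seed: int = 0) -> ScanResult:
    """Single-marker association scan with a permutation threshold.

    ``traits`` is a per-line Series (line means); ``genotypes`` a line x
    marker frame coded +1/-1 (Drysdale/Gladius) with NaN for missing;
    ``covariates`` optional per-line columns (e.g. phenology-gene
    genotypes) whose effect is removed before testing each marker.  The
    additive effect is half the difference between Drysdale and Gladius
    class means (positive = Drysdale allele increases the trait).
    """
    lines, y, G, C = _prepare(traits, genotypes, covariates)
    F, df2, poly = _marker_F(y, G, C)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(F, 1, df2)
    # additive effect from raw class means
    eff = np.full(G.shape[1], np.nan)
    for j in range(G.shape[1]):
        gj = G[:, j]
        a_mask, b_mask = gj == 1, gj == -1
        if a_mask.any() and b_mask.any():
            eff[j] = 0.5 * (y[a_mask].mean() - y[b_mask].mean())
    if threshold is None:
        threshold = permutation_threshold(
            traits, genotypes, covariates=covariates,
            n_perm=n_permutations, alpha=alpha, seed=seed)
    table = pd.DataFrame({
        "marker": genotypes.columns,
        "F": F,
        "p": p,
        "effect": eff,
        "skipped_monomorphic": ~poly,
    })
    if marker_map is not None:
        table = table.merge(marker_map, on="marker", how="left")
    table["above_threshold"] = table["F"] > threshold
    return ScanResult(table=table, threshold=float(threshold), alpha=alpha,
                      n_permutations=n_permutations)


def permutation_threshold(traits: pd.Series, genotypes: pd.DataFrame,
                          covariates: pd.DataFrame | None = None,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Genome-wide F threshold: (1-alpha) quantile of the max-over-markers
    statistic under random permutation of the phenotypes across lines."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    lines, y, G, C = _prepare(traits, genotypes, covariates)
    rng = np.random.default_rng(seed)
    n, M = G.shape
    X = G.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    poly = np.nanstd(X, axis=0) > 0
    X = X[:, poly]
    q = 0 if C is None else C.shape[1]
    df2 = n - q - 2
    Xr = _residualize(X, C)
    Xn = Xr / np.linalg.norm(Xr, axis=0, keepdims=True)
    # permute raw phenotypes, then residualize each permuted vector
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]
    Yr = _residualize(perms, C)
    Yn = Yr / np.linalg.norm(Yr, axis=0, keepdims=True)
    r2 = np.clip((Xn.T @ Yn) ** 2, 0.0, 1.0 - 1e-12)
    Fmax = (r2 * df2 / (1.0 - r2)).max(axis=0)
    return float(np.quantile(Fmax, 1.0 - alpha))


# ---------------------------------------------------------------------------
# allele-group bootstrap curves


def allele_group_bootstrap(fits: pd.DataFrame, marker_calls: pd.Series,
                           t_grid: np.ndarray, n_boot: int = 1000,
                           min_class_size: int = 10,
                           seed: int = 0) -> pd.DataFrame:
    """Bootstrap mean logistic growth curves per allele class.

    ``fits`` has one row per line with columns V_final, K, t0 (fitted
    logistic parameters, typically line means); ``marker_calls`` maps line
    to +1/-1.  Lines are resampled with replacement (no refitting), the
    fitted curves are averaged on ``t_grid``, and the bootstrap mean and
    SD envelope are returned per class (long format: allele, t, mean, sd,
    n_lines).
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    out = []
    for allele, label in ((1, "A"), (-1, "B")):
        lines = marker_calls[marker_calls == allele].index
        sub = fits.loc[fits.index.intersection(lines)]
        n = len(sub)
        if n < min_class_size:
            raise ValueError(
                f"allele class {label} has {n} lines, below minimum {min_class_size}")
        Vf = sub["V_final"].to_numpy()[:, None]
        K = sub["K"].to_numpy()[:, None]
        t0 = sub["t0"].to_numpy()[:, None]
        curves = Vf / (1.0 + np.exp(-K * (t_grid[None, :] - t0)))
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = curves[idx].mean(axis=1)        # n_boot x grid
        out.append(pd.DataFrame({
            "allele": label,
            "t": t_grid,
            "mean": boot_means.mean(axis=0),
            "sd": boot_means.std(axis=0, ddof=1),
            "n_lines": n,
        }))
    return pd.concat(out, ignore_index=True)
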