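"""Calibration of projected areas against destructive harvest measurements.

For each biological variable (oven-dry biomass, fresh plant weight,
planimeter leaf area) the full second-order two-predictor linear model

    Y ~ 1 + side + top + side^2 + top^2 + side:top

and all 32 sub-models (intercept always present) are fitted by ordinary
least squares on the destructive-harvest samples, compared by BIC, and the
lowest-BIC model is retained.  One shared model per trait is applied to
both watering treatments so that treatment responses are comparable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: The five candidate predictors; the intercept is always included.
TERMS = ("side", "top", "side2", "top2", "side:top")

TRAITS = ("biomass", "plant_weight", "leaf_area")

NEG_INF_BIC = float("-inf")


class SingularFitError(ValueError):
    """Raised when the calibration design matrix is rank deficient."""


@dataclass
class CalibrationModel:
    """A fitted area-to-trait calibration model.

    ``coefficients`` holds the intercept first, then one value per entry
    of ``terms`` in order.  ``rss`` is the residual sum of squares on the
    fitting sample of size ``n``.
    """

    trait: str
    terms: tuple[str, ...]
    coefficients: np.ndarray
    n: int
    rss: float
    term_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return bic(self)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "terms": list(self.terms),
            "coefficients": [float(c) for c in self.coefficients],
            "n": self.n,
            "rss": float(self.rss),
            "bic": float(self.bic),
            "term_pvalues": {k: float(v) for k, v in self.term_pvalues.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            trait=d["trait"],
            terms=tuple(d["terms"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            n=int(d["n"]),
            rss=float(d["rss"]),
            term_pvalues=dict(d.get("term_pvalues", {})),
        )


def design_columns(side: np.ndarray, top: np.ndarray,
                   terms: tuple[str, ...]) -> np.ndarray:
    """Build the design matrix (with intercept) for a term subset."""
    side = np.asarray(side, dtype=float)
    top = np.asarray(top, dtype=float)
    cols = {"side": side, "top": top, "side2": side ** 2,
            "top2": top ** 2, "side:top": side * top}
    X = np.column_stack([np.ones_like(side)] + [cols[t] for t in terms])
    return X


def enumerate_candidates() -> list[tuple[str, ...]]:
    """All 2^5 subsets of the five predictors, intercept-only included."""
    out: list[tuple[str, ...]] = []
    for r in range(len(TERMS) + 1):
        out.extend(itertools.combinations(TERMS, r))
    return out


def fit_linear(samples: pd.DataFrame, terms: tuple[str, ...],
               trait: str) -> CalibrationModel:
    """Ordinary least squares fit of one term subset for one trait.

    ``samples`` needs columns ``side_area``, ``top_area`` and the trait
    column.  Raises :class:`SingularFitError` on a rank-deficient design,
    naming the collinear terms.
    """
    terms = tuple(terms)
    y = samples[trait].to_numpy(dtype=float)
    X = design_columns(samples["side_area"].to_numpy(),
                       samples["top_area"].to_numpy(), terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"need more than {p} samples to fit terms {terms}, got {n}"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError(
            f"rank-deficient design for terms {terms}: collinear columns"
        )
    res = sm.OLS(y, X).fit()
    pvals = {t: res.pvalues[i + 1] for i, t in enumerate(terms)}
    return CalibrationModel(
        trait=trait,
        terms=terms,
        coefficients=np.asarray(res.params, dtype=float),
        n=n,
        rss=float(res.ssr),
        term_pvalues=pvals,
    )


def bic(model: CalibrationModel) -> float:
    """Gaussian BIC: n*ln(rss/n) + k*ln(n), k counting intercept and
    residual variance (k = |terms| + 2).  Lower is better.  An exact fit
    (rss == 0) returns -inf as a flagged sentinel.
    """
    n = model.n
    k = len(model.terms) + 2
    if model.rss <= 0:
        logger.warning("exact fit (rss=0) for terms %s: BIC sentinel -inf",
                       model.terms)
        return NEG_INF_BIC
    return n * math.log(model.rss / n) + k * math.log(n)


def select_model(samples: pd.DataFrame, trait: str) -> CalibrationModel:
    """Fit all 32 candidate term subsets and return the lowest-BIC model.

    Treatments are pooled: the selected model is applied unchanged to
    both watering regimes.  Singular candidates are skipped with a logged
    warning; ties in BIC are broken toward fewer terms, then enumeration
    order.
    """
    best: CalibrationModel | None = None
    best_key: tuple | None = None
    for i, terms in enumerate(enumerate_candidates()):
        try:
            m = fit_linear(samples, terms, trait)
        except (SingularFitError, ValueError) as exc:
            logger.warning("skipping candidate %s: %s", terms, exc)
            continue
        key = (bic(m), len(m.terms), i)
        if best_key is None or key < best_key:
            best, best_key = m, key
    if best is None:
        raise RuntimeError(f"no calibration candidate could be fitted for {trait}")
    return best


def predict_trait(model: CalibrationModel, side_area, top_area) -> np.ndarray:
    """Predict the calibrated trait from projected areas (mm^2).

    Predictions are returned raw; negative values (possible for very small
    plants) are flagged by the caller, never clipped here, because clipping
    would bias the downstream growth-curve fits.
    """
    side = np.atleast_1d(np.asarray(side_area, dtype=float))
    top = np.atleast_1d(np.asarray(top_area, dtype=float))
    X = design_columns(side, top, model.terms)
    pred = X @ model.coefficients
    if np.isscalar(side_area) or np.asarray(side_area).ndim == 0:
        return float(pred[0])
    return pred


def significance_stars(p: float) -> str:
    """Per-term significance stars for the calibration summary."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "(.)"
    return ""


def calibrate_all(samples: pd.DataFrame,
                  per_treatment: bool = False) -> dict[str, CalibrationModel]:
    """Select one calibration model per trait on the pooled harvest data.

    ``per_treatment=True`` fits separate models per watering treatment and
    returns keys like ``"biomass/drought"``; the default (pooled) matches
    the published procedure.
    """
    models: dict[str, CalibrationModel] = {}
    if per_treatment:
        for trt, grp in samples.groupby("treatment"):
            for trait in TRAITS:
                models[f"{trait}/{trt}"] = select_model(grp, trait)
    else:
        for trait in TRAITS:
            models[trait] = select_model(samples, trait)
    return models
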