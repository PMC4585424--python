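"""Growth-curve fitting on the thermal-time axis.

Candidate models for a trait V(t) (biomass g, plant weight g, or leaf
area mm^2 versus thermal time d20):

    linear        a + b*t
    exponential   a * exp(b*t)
    logistic3     Vf / (1 + exp(-K*(t - t0)))
    logistic4     c + (Vf - c) / (1 + exp(-K*(t - t0)))
    richards4     Vf / (1 + nu*exp(-K*(t - t0)))**(1/nu)
    richards5     c + (Vf - c) / (1 + nu*exp(-K*(t - t0)))**(1/nu)
    gompertz4     a + c * exp(-exp(-b*(t - m)))
    weibull3      Vf * (1 - exp(-(t/lam)**k))
    weibull4      c + (Vf - c) * (1 - exp(-(t/lam)**k))

Each is fitted by nonlinear least squares from a self-start estimate plus
three jittered restarts (several of these models converge fragilely on
real data), and candidates are compared by BIC.  The three-parameter
logistic is the expected winner on platform data; its parameters have
direct biological readings: t0 is the inflexion point (vegetative to
reproductive transition, Tx) and K is the maximum relative growth rate
(K_RGR / K_RER).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthFit",
    "MODELS",
    "self_start_logistic",
    "fit_growth",
    "select_growth_model",
    "predict",
    "growth_rate",
    "relative_growth_rate",
    "window_averages",
]


@dataclass
class GrowthFit:
    """Result of fitting one candidate model to one plant/trait series."""

    model_kind: str
    params: dict[str, float]
    rss: float
    n: int
    converged: bool
    message: str = ""

    @property
    def bic(self) -> float:
        if not self.converged:
            return float("inf")
        k = len(self.params) + 1  # + residual variance
        if self.rss <= 0:
            return float("-inf")
        return self.n * math.log(self.rss / self.n) + k * math.log(self.n)


# ---------------------------------------------------------------------------
# model functions


def _logistic3(t, Vf, K, t0):
    return Vf / (1.0 + np.exp(-K * (t - t0)))


def _logistic4(t, c, Vf, K, t0):
    return c + (Vf - c) / (1.0 + np.exp(-K * (t - t0)))


def _richards4(t, Vf, K, t0, nu):
    nu = max(nu, 1e-6)
    return Vf / (1.0 + nu * np.exp(-K * (t - t0))) ** (1.0 / nu)


def _richards5(t, c, Vf, K, t0, nu):
    nu = max(nu, 1e-6)
    return c + (Vf - c) / (1.0 + nu * np.exp(-K * (t - t0))) ** (1.0 / nu)


def _gompertz4(t, a, c, b, m):
    return a + c * np.exp(-np.exp(-b * (t - m)))


def _weibull3(t, Vf, lam, k):
    lam = max(lam, 1e-9)
    tt = np.maximum(np.asarray(t, dtype=float), 0.0)
    return Vf * (1.0 - np.exp(-((tt / lam) ** max(k, 1e-6))))


def _weibull4(t, c, Vf, lam, k):
    return c + (_weibull3(t, Vf - c, lam, k))


def _linear(t, a, b):
    return a + b * np.asarray(t, dtype=float)


def _exponential(t, a, b):
    return a * np.exp(b * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# self-start heuristics


def self_start_logistic(t, v):
    """Initial (Vf, K, t0) for the 3-parameter logistic.

    Vf0 is 5% above the observed maximum; t0_0 the time of half-maximum;
    K0 the slope of logit(v/Vf0) against t.  Returns None (non-fittable)
    for degenerate series (constant values or < 3 distinct positive
    points).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    pos = v > 0
    if np.unique(v).size < 3 or pos.sum() < 3 or np.ptp(v) <= 0:
        return None
    Vf0 = 1.05 * float(np.max(v))
    t0_0 = float(t[np.argmin(np.abs(v - Vf0 / 2.0))])
    frac = np.clip(v[pos] / Vf0, 1e-6, 1 - 1e-6)
    logit = np.log(frac / (1.0 - frac))
    tp = t[pos]
    if np.ptp(tp) <= 0:
        return None
    slope = float(np.polyfit(tp, logit, 1)[0])
    K0 = slope if slope > 0 else 0.1
    return (Vf0, K0, t0_0)


def _start_linear(t, v):
    b, a = np.polyfit(t, v, 1)
    return (float(a), float(b))


def _start_exponential(t, v):
    pos = v > 0
    if pos.sum() < 3:
        return None
    b, loga = np.polyfit(t[pos], np.log(v[pos]), 1)
    return (float(np.exp(loga)), float(b))


def _start_logistic4(t, v):
    s = self_start_logistic(t, v - np.min(v) + 1e-9)
    if s is None:
        return None
    Vf, K, t0 = s
    c = float(np.min(v))
    return (c, c + Vf, K, t0)


def _start_richards4(t, v):
    s = self_start_logistic(t, v)
    return None if s is None else (*s, 1.0)


def _start_richards5(t, v):
    s = _start_logistic4(t, v)
    return None if s is None else (*s, 1.0)


def _start_gompertz4(t, v):
    s = self_start_logistic(t, v)
    if s is None:
        return None
    Vf, K, t0 = s
    return (float(np.min(v)), Vf - float(np.min(v)), K, t0)


def _start_weibull3(t, v):
    if np.max(v) <= 0 or np.ptp(v) <= 0:
        return None
    Vf0 = 1.05 * float(np.max(v))
    lam0 = float(t[np.argmin(np.abs(v - Vf0 / 2.0))])
    return (Vf0, max(lam0, 1e-3), 2.0)


def _start_weibull4(t, v):
    s = _start_weibull3(t, v - np.min(v) + 1e-9)
    if s is None:
        return None
    Vf, lam, k = s
    c = float(np.min(v))
    return (c, c + Vf, lam, k)


#: name -> (function, parameter names, self-start)
MODELS = {
    "linear": (_linear, ("a", "b"), _start_linear),
    "exponential": (_exponential, ("a", "b"), _start_exponential),
    "logistic3": (_logistic3, ("V_final", "K", "t0"), self_start_logistic),
    "logistic4": (_logistic4, ("c", "V_final", "K", "t0"), _start_logistic4),
    "richards4": (_richards4, ("V_final", "K", "t0", "nu"), _start_richards4),
    "richards5": (_richards5, ("c", "V_final", "K", "t0", "nu"), _start_richards5),
    "gompertz4": (_gompertz4, ("a", "c", "b", "m"), _start_gompertz4),
    "weibull3": (_weibull3, ("V_final", "lam", "k"), _start_weibull3),
    "weibull4": (_weibull4, ("c", "V_final", "lam", "k"), _start_weibull4),
}


# ---------------------------------------------------------------------------
# fitting


def fit_growth(t, v, model_kind: str, n_restarts: int = 3,
               seed: int = 0) -> GrowthFit:
    """Nonlinear least-squares fit of one candidate model.

    The self-start estimate is refined with scipy's trust-region
    reflective solver; ``n_restarts`` jittered restarts guard against
    fragile convergence and the best residual is kept.  Optimizer failure
    or a degenerate series yields ``converged=False`` with a diagnostic
    message, never an exception.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size != v.size:
        raise ValueError("t and v must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("thermal-time axis must be strictly increasing")
    func, names, start = MODELS[model_kind]
    if t.size < len(names) + 2:
        return GrowthFit(model_kind, {}, float("nan"), t.size, False,
                         "too few points")
    theta0 = start(t, v)
    if theta0 is None:
        return GrowthFit(model_kind, {}, float("nan"), t.size, False,
                         "non-fittable (degenerate series)")

    rng = np.random.default_rng(seed)
    scale = np.maximum(np.abs(np.asarray(theta0, dtype=float)), 1e-3)
    best = None
    starts = [np.asarray(theta0, dtype=float)]
    for _ in range(n_restarts):
        starts.append(theta0 + scale * rng.normal(0.0, 0.1, size=len(theta0)))
    ssv = float(np.sum(v ** 2))
    for th0 in starts:
        if best is not None and best[0] < 1e-14 * max(ssv, 1e-300):
            break  # essentially exact fit; restarts cannot improve

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(
                    lambda th: func(t, *th) - v, th0,
                    method="trf", max_nfev=2000,
                )
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun ** 2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x)
    if best is None:
        return GrowthFit(model_kind, {}, float("nan"), t.size, False,
                         "optimizer failed from all starts")
    rss, theta = best
    params = {k: float(x) for k, x in zip(names, theta)}
    ok = True
    msg = ""
    if model_kind == "logistic3":
        if params["V_final"] <= 0 or params["K"] <= 0:
            ok, msg = False, "non-physical logistic parameters"
        elif not (t.min() - 50 <= params["t0"] <= t.max() + 50):
            ok, msg = False, "inflexion point far outside data range"
    return GrowthFit(model_kind, params, rss, t.size, ok, msg)


def select_growth_model(t, v, candidates=("linear", "exponential", "logistic3"),
                        seed: int = 0) -> GrowthFit | None:
    """Lowest-BIC converged candidate; ties favour fewer parameters then
    the fixed candidate order.  Returns None when nothing converges."""
    best, best_key = None, None
    for i, kind in enumerate(candidates):
        fit = fit_growth(t, v, kind, seed=seed)
        if not fit.converged:
            continue
        key = (fit.bic, len(fit.params), i)
        if best_key is None or key < best_key:
            best, best_key = fit, key
    return best


def predict(fit: GrowthFit, t):
    """Evaluate a fitted model at thermal times t."""
    func, names, _ = MODELS[fit.model_kind]
    out = func(np.asarray(t, dtype=float), *[fit.params[k] for k in names])
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# derived quantities (closed forms for the 3-parameter logistic)


def growth_rate(fit: GrowthFit, t):
    """Absolute growth rate dV/dt.

    Closed form K*V*(1 - V/V_final) for the 3-parameter logistic; a
    central finite difference for the other models.
    """
    t = np.asarray(t, dtype=float)
    if fit.model_kind == "logistic3":
        V = predict(fit, t)
        out = fit.params["K"] * V * (1.0 - V / fit.params["V_final"])
    elif fit.model_kind == "linear":
        out = np.full_like(t, fit.params["b"], dtype=float)
    else:
        h = 1e-4
        out = (predict(fit, t + h) - predict(fit, t - h)) / (2 * h)
    return float(out) if np.ndim(out) == 0 else out


def relative_growth_rate(fit: GrowthFit, t):
    """Relative growth rate (dV/dt)/V; for the logistic, K*(1 - V/V_final),
    monotone decreasing with supremum K (hence K = maximum RGR)."""
    t = np.asarray(t, dtype=float)
    if fit.model_kind == "logistic3":
        V = predict(fit, t)
        out = fit.params["K"] * (1.0 - V / fit.params["V_final"])
    else:
        V = predict(fit, t)
        out = growth_rate(fit, t) / V
    return float(out) if np.ndim(out) == 0 else out


def window_averages(fit: GrowthFit, window=(35.0, 50.0),
                    rgr_mode: str = "window_mean"):
    """Average growth rate and average relative rate over a thermal window.

    Growth_AVE = (V(end) - V(start)) / (end - start); the relative rate is
    either the trapezoid mean over a 0.1 d20 grid (default) or the value
    at the window midpoint.  Also returns a flag when the window lies
    outside the plausible support of the fit.
    """
    a, b = float(window[0]), float(window[1])
    if not b > a:
        raise ValueError(f"degenerate window [{a}, {b}]")
    growth_ave = (predict(fit, b) - predict(fit, a)) / (b - a)
    if rgr_mode == "midpoint":
        rgr = float(relative_growth_rate(fit, 0.5 * (a + b)))
    else:
        grid = np.arange(a, b + 1e-9, 0.1)
        rgr = float(np.trapezoid(relative_growth_rate(fit, grid), grid) / (b - a))
    flagged = False
    if fit.model_kind == "logistic3":
        t0 = fit.params["t0"]
        if t0 < a - 100 or t0 > b + 100:
            flagged = True
    return float(growth_ave), rgr, flagged
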