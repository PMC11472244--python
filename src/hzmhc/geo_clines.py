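"""Sigmoid geographic cline fitting, model selection and effect sizes.

A geographic cline describes the sigmoid transition of population mean
ancestry along a transect.  The smooth (tail-free) cline is

    p(x) = pmin + (pmax - pmin) * (1 + tanh(2 (x - c) / w)) / 2,

with center c (km), width w (km, inverse of the maximum slope), and
ancestry asymptotes pmin, pmax.  Three nested models are fitted by maximum
likelihood and compared by AIC, alongside a flat no-cline null:

- "none":  ends fixed at 0 and 1 (parameters c, w)
- "fixed": equal admixture e at both ends, pmin = e, pmax = 1 - e (c, w, e)
- "free":  pmin and pmax estimated separately (c, w, pmin, pmax)

The default likelihood is binomial on effective ancestry counts: a
population mean ancestry y over n diploid individuals is treated as y * 2n
successes in 2n trials, the natural error model for an admixture
proportion (fractional counts are allowed, i.e. quasi-binomial for
continuous hybrid indices).  A Gaussian alternative on population means
with per-population variance sd^2 / n (floored) is available, but with
empirical variances it over-weights monomorphic tail populations and
narrows the estimated width.  Support intervals are profile-likelihood
ranges within 2 log-likelihood units of the maximum, conventionally read
as ~95% CIs.

Cross-zone contrasts: Hedges g for the MHC vs genome-wide width difference
(standard deviations recovered from the 2-log-likelihood intervals), and
the cline-center shift signed positive toward the less MHC-diverse species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

__all__ = [
    "GeographicClineFit",
    "sigmoid_cline",
    "fit_geographic_cline",
    "select_cline_model",
    "hedges_g_from_intervals",
    "center_shift",
]

_VAR_FLOOR = 1e-4
_MODELS = ("none", "fixed", "free", "no_cline")


def sigmoid_cline(
    x: float | np.ndarray, c: float, w: float, pmin: float = 0.0, pmax: float = 1.0
) -> float | np.ndarray:
    """Expected ancestry at position ``x`` under the tanh cline."""
    if w <= 0:
        raise ValueError("cline width must be positive")
    x = np.asarray(x, dtype=float)
    p = pmin + (pmax - pmin) * 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))
    return float(p) if p.ndim == 0 else p


@dataclass
class GeographicClineFit:
    model: str
    center: float
    width: float
    pmin: float
    pmax: float
    log_likelihood: float
    aic: float
    support_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    increasing: bool = True
    converged: bool = True
    excluded_no_cline: bool = False

    @property
    def n_params(self) -> int:
        return {"none": 2, "fixed": 3, "free": 4, "no_cline": 1}[self.model]

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.model == "no_cline":
            return np.full_like(np.asarray(x, dtype=float), self.pmin)
        xx = np.asarray(x, dtype=float)
        if not self.increasing:
            # decreasing transect fitted on mirrored axis
            return sigmoid_cline(-xx, -self.center, self.width, self.pmin, self.pmax)
        return sigmoid_cline(xx, self.center, self.width, self.pmin, self.pmax)


def _as_table(populations) -> pd.DataFrame:
    if isinstance(populations, pd.DataFrame):
        df = populations.copy()
    else:
        df = pd.DataFrame(populations, columns=["x", "mean", "n", "sd"])
    required = {"x", "mean", "n", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"population table needs columns {sorted(required)}")
    return df.sort_values("x").reset_index(drop=True)


def _variances(df: pd.DataFrame) -> np.ndarray:
    return np.maximum(df["sd"].to_numpy() ** 2 / df["n"].to_numpy(), _VAR_FLOOR)


def _gauss_loglik(pred: np.ndarray, mean: np.ndarray, var: np.ndarray) -> float:
    resid = mean - pred
    return float(-0.5 * np.sum(resid**2 / var + np.log(2 * np.pi * var)))


def _binom_loglik(pred: np.ndarray, mean: np.ndarray, trials: np.ndarray) -> float:
    """Quasi-binomial log-likelihood of mean ancestry y over ``trials`` = 2n
    effective draws: sum 2n * (y log p + (1-y) log(1-p)), up to a constant."""
    p = np.clip(pred, 1e-12, 1.0 - 1e-12)
    return float(np.sum(trials * (mean * np.log(p) + (1.0 - mean) * np.log1p(-p))))


def _unpack(theta: np.ndarray, model: str) -> tuple[float, float, float, float]:
    if model == "none":
        return theta[0], theta[1], 0.0, 1.0
    if model == "fixed":
        return theta[0], theta[1], theta[2], 1.0 - theta[2]
    return theta[0], theta[1], theta[2], theta[3]


def _fit_one(x, mean, model, x_lo, x_hi, loglik):
    span = x_hi - x_lo

    def nll(theta):
        c, w, pmin, pmax = _unpack(theta, model)
        return -loglik(sigmoid_cline(x, c, w, pmin, pmax))

    bounds = [(x_lo - span, x_hi + span), (1e-3, 10 * span)]
    if model == "fixed":
        bounds.append((0.0, 0.5))
    elif model == "free":
        bounds += [(0.0, 1.0), (0.0, 1.0)]

    # multi-start: centers at quantiles of x and at the 0.5-crossing
    cross = x[np.argmin(np.abs(mean - 0.5))]
    centers = np.unique(np.concatenate([np.quantile(x, [0.25, 0.5, 0.75]), [cross]]))
    widths = span * np.array([0.02, 0.1, 0.3])
    best = None
    for c0 in centers:
        for w0 in widths:
            theta0 = [c0, w0]
            if model == "fixed":
                theta0.append(0.01)
            elif model == "free":
                theta0 += [0.01, 0.99]
            res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    return best, bounds, nll


def _profile_interval(nll, theta_hat, bounds, idx, ll_max, drop=2.0):
    """Profile-likelihood interval for parameter ``idx`` at a 2-unit drop."""
    free = [j for j in range(len(theta_hat)) if j != idx]

    def profile_nll(v):
        if not free:
            return nll(np.array([v]))
        def inner(sub):
            theta = np.empty(len(theta_hat))
            theta[idx] = v
            theta[free] = sub
            return nll(theta)
        res = minimize(inner, theta_hat[free], method="L-BFGS-B",
                       bounds=[bounds[j] for j in free])
        return res.fun

    target = -ll_max + drop
    out = []
    for direction, limit in ((-1, bounds[idx][0]), (1, bounds[idx][1])):
        v_hat = theta_hat[idx]
        step = max(abs(v_hat) * 0.05, (bounds[idx][1] - bounds[idx][0]) * 0.005)
        v, prev = v_hat, v_hat
        found = None
        for _ in range(60):
            prev = v
            v = v + direction * step
            if (direction < 0 and v <= limit) or (direction > 0 and v >= limit):
                v = limit
            if profile_nll(v) > target:
                found = (prev, v) if direction > 0 else (v, prev)
                break
            if v == limit:
                break
            step *= 1.6
        if found is None:
            out.append(limit)
        else:
            lo, hi = found
            try:
                out.append(brentq(lambda u: profile_nll(u) - target, lo, hi, xtol=1e-4))
            except ValueError:
                out.append(limit)
    return (float(min(out[0], theta_hat[idx])), float(max(out[1], theta_hat[idx])))


def fit_geographic_cline(
    populations,
    model: str = "none",
    compute_intervals: bool = True,
    likelihood: str = "binomial",
) -> GeographicClineFit:
    """ML fit of one cline model to population means.

    ``populations``: DataFrame (or records) with columns x, mean, n, sd.
    ``likelihood``: "binomial" (default) treats each population mean as
    2n effective ancestry draws; "gaussian" uses per-population variance
    sd^2/n floored at 1e-4.  Decreasing transects are detected and fitted
    on the mirrored axis; the reported center is on the original axis and
    the width is unchanged.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    if likelihood not in ("binomial", "gaussian"):
        raise ValueError("likelihood must be 'binomial' or 'gaussian'")
    df = _as_table(populations)
    min_pops = {"none": 4, "fixed": 5, "free": 6, "no_cline": 2}[model]
    if len(df) < min_pops:
        raise ValueError(f"model {model!r} needs >= {min_pops} populations, got {len(df)}")
    x = df["x"].to_numpy(dtype=float)
    mean = df["mean"].to_numpy(dtype=float)
    if likelihood == "gaussian":
        var = _variances(df)
        loglik = lambda pred, m=mean, v=var: _gauss_loglik(pred, m, v)
    else:
        trials = 2.0 * df["n"].to_numpy(dtype=float)
        loglik = lambda pred, m=mean, t=trials: _binom_loglik(pred, m, t)

    if model == "no_cline":
        if likelihood == "gaussian":
            level = float(np.sum(mean / var) / np.sum(1.0 / var))
        else:
            level = float(np.average(mean, weights=trials))
        ll = loglik(np.full_like(mean, np.clip(level, 1e-12, 1 - 1e-12)))
        return GeographicClineFit("no_cline", np.nan, np.nan, level, level, ll, 2 * 1 - 2 * ll)

    increasing = bool(np.corrcoef(x, mean)[0, 1] >= 0)
    x_fit = x if increasing else -x
    order = np.argsort(x_fit)
    x_fit, mean_fit = x_fit[order], mean[order]
    if likelihood == "gaussian":
        v_sorted = var[order]
        loglik = lambda pred, m=mean_fit, v=v_sorted: _gauss_loglik(pred, m, v)
    else:
        t_sorted = (2.0 * df["n"].to_numpy(dtype=float))[order]
        loglik = lambda pred, m=mean_fit, t=t_sorted: _binom_loglik(pred, m, t)

    res, bounds, nll = _fit_one(x_fit, mean_fit, model, x_fit.min(), x_fit.max(), loglik)
    theta_hat = res.x
    ll_max = -res.fun
    c, w, pmin, pmax = _unpack(theta_hat, model)
    k = {"none": 2, "fixed": 3, "free": 4}[model]
    intervals: dict[str, tuple[float, float]] = {}
    if compute_intervals:
        names = ["center", "width"] + (["tail"] if model == "fixed" else ["pmin", "pmax"] if model == "free" else [])
        for j, name in enumerate(names):
            intervals[name] = _profile_interval(nll, theta_hat, bounds, j, ll_max)
        if not increasing and "center" in intervals:
            lo, hi = intervals["center"]
            intervals["center"] = (-hi, -lo)
    center = c if increasing else -c
    return GeographicClineFit(
        model, float(center), float(w), float(pmin), float(pmax),
        float(ll_max), 2 * k - 2 * ll_max, intervals, increasing, bool(res.success),
    )


def select_cline_model(fits: list[GeographicClineFit]) -> GeographicClineFit:
    """Minimum-AIC model choice.  When the flat no-cline null wins, the fit
    is flagged ``excluded_no_cline`` — the transect is dropped from cline
    comparisons rather than contributing a meaningless center and width."""
    if len(fits) < 2:
        raise ValueError("need at least 2 candidate fits")
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    if best.model == "no_cline":
        best.excluded_no_cline = True
    return best


def hedges_g_from_intervals(
    est1: float,
    ci1: tuple[float, float],
    est2: float,
    ci2: tuple[float, float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Hedges-g-style standardized difference of two parameter estimates.

    The 2-log-likelihood intervals are conservatively read as 95% CIs, so
    sd_i = (hi - lo) / (2 * 1.96); g = (est1 - est2) / sqrt((sd1^2 + sd2^2)/2).
    No small-sample correction is applied (each "group" is a single
    estimate).  The CI of g comes from a parametric bootstrap drawing the
    two estimates from their Gaussian sampling distributions with the
    pooled sd held fixed.
    """
    for est, ci in ((est1, ci1), (est2, ci2)):
        if not (ci[0] <= est <= ci[1]) or not np.all(np.isfinite(ci)):
            raise ValueError(f"CI {ci} does not contain estimate {est} or is not finite")
    sd1 = (ci1[1] - ci1[0]) / (2 * 1.959963984540054)
    sd2 = (ci2[1] - ci2[0]) / (2 * 1.959963984540054)
    pooled = np.sqrt((sd1**2 + sd2**2) / 2)
    if pooled == 0:
        raise ValueError("zero pooled sd")
    g = (est1 - est2) / pooled
    rng = np.random.default_rng(seed)
    draws = (rng.normal(est1, sd1, n_boot) - rng.normal(est2, sd2, n_boot)) / pooled
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(g), (float(lo), float(hi))


def center_shift(
    fit_mhc: GeographicClineFit,
    fit_gw: GeographicClineFit,
    less_diverse_side: str,
) -> float:
    """Signed MHC-vs-genome-wide center difference in km, positive when the
    MHC cline center is shifted toward the less MHC-diverse species."""
    if less_diverse_side not in ("increasing_x", "decreasing_x"):
        raise ValueError("less_diverse_side must be 'increasing_x' or 'decreasing_x'")
    for f in (fit_mhc, fit_gw):
        if f.model == "no_cline" or not np.isfinite(f.center):
            raise ValueError("center shift requires valid cline fits with finite centers")
    diff = fit_mhc.center - fit_gw.center
    return float(diff if less_diverse_side == "increasing_x" else -diff)
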