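"""Barton's concordance genomic clines: MHC ancestry vs genome-wide ancestry.

In admixed individuals, locus-specific introgression shows up as a
departure of MHC ancestry (pMHC) from genome-wide ancestry (p-bar).  The
concordance curve

    pMHC = p + 2 p q (alpha + (p - q) beta),    q = 1 - p,

passes through (0, 0) and (1, 1) for any parameters: individuals without
genome-wide admixture carry no information and are excluded from the fit.
alpha measures the cline shift (an excess of MHC ancestry from one
species); beta the relative rate of transition, with beta < 0 meaning a
slower MHC transition, i.e. more MHC admixture than the genome-wide
expectation.  Parameters are estimated by Gaussian maximum likelihood on
the residuals with profile 2-log-likelihood support intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize

from .data_model import ZoneConfig

__all__ = ["GenomicClineFit", "barton_curve", "fit_genomic_cline", "orient_alpha"]

_PARAM_BOX = 2.0  # |alpha|, |beta| bound; beyond this the curve folds severely


def barton_curve(
    pbar: float | np.ndarray, alpha: float, beta: float, clamp: bool = True
) -> float | np.ndarray:
    """Expected MHC ancestry at genome-wide ancestry ``pbar``.

    The quadratic can leave [0, 1] for large |alpha|, |beta|; values are
    clamped by default since ancestry proportions are bounded.
    """
    p = np.asarray(pbar, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pbar outside [0, 1]")
    q = 1.0 - p
    out = p + 2.0 * p * q * (alpha + (p - q) * beta)
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GenomicClineFit:
    alpha: float
    beta: float
    log_likelihood: float
    sigma: float
    support_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_admixed_used: int = 0
    oriented_to_more_diverse: bool = False


def _nll_factory(pbar: np.ndarray, pmhc: np.ndarray):
    n = len(pbar)

    def nll(theta: np.ndarray) -> float:
        resid = pmhc - barton_curve(pbar, theta[0], theta[1])
        s2 = max(float(np.mean(resid**2)), 1e-12)  # profiled-out ML variance
        return 0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

    return nll


def fit_genomic_cline(
    individuals,
    admixture_window: tuple[float, float] = (0.0, 1.0),
    compute_intervals: bool = True,
) -> GenomicClineFit:
    """ML fit of (alpha, beta) to per-individual (pbar, pMHC) pairs.

    ``individuals``: iterable of (pbar, pMHC) or an (n, 2) array.
    Individuals with pbar at exactly 0 or 1 never contribute;
    ``admixture_window`` optionally narrows further (e.g. (0.03, 0.97) to
    mirror the 3% genome-wide admixture rule symmetrically).
    """
    arr = np.asarray(list(individuals) if not isinstance(individuals, np.ndarray) else individuals, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("individuals must be (pbar, pMHC) pairs")
    lo, hi = admixture_window
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    keep = (arr[:, 0] > lo) & (arr[:, 0] < hi) & (arr[:, 0] > 0) & (arr[:, 0] < 1)
    sub = arr[keep]
    if len(sub) == 0:
        raise ValueError(
            "no admixed individuals: distribution of genome-wide ancestry is strongly bimodal"
        )
    if len(sub) < 5:
        raise ValueError(f"need >= 5 admixed individuals, got {len(sub)}")
    pbar, pmhc = sub[:, 0], sub[:, 1]
    nll = _nll_factory(pbar, pmhc)
    bounds = [(-_PARAM_BOX, _PARAM_BOX)] * 2
    best = None
    for a0 in (-0.5, 0.0, 0.5):
        for b0 in (-0.5, 0.0, 0.5):
            res = minimize(nll, [a0, b0], method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta = best.x
    ll_max = -best.fun
    resid = pmhc - barton_curve(pbar, alpha, beta)
    sigma = float(np.sqrt(np.mean(resid**2)))

    intervals: dict[str, tuple[float, float]] = {}
    if compute_intervals:
        for j, name in enumerate(("alpha", "beta")):
            intervals[name] = _profile_interval_2p(nll, best.x, bounds, j, ll_max)
    return GenomicClineFit(float(alpha), float(beta), float(ll_max), sigma, intervals, len(sub))


def _profile_interval_2p(nll, theta_hat, bounds, idx, ll_max, drop: float = 2.0):
    other = 1 - idx

    def profile_nll(v: float) -> float:
        def inner(u):
            theta = np.empty(2)
            theta[idx], theta[other] = v, u[0]
            return nll(theta)
        res = minimize(inner, [theta_hat[other]], method="L-BFGS-B", bounds=[bounds[other]])
        return res.fun

    target = -ll_max + drop
    ends = []
    for direction, limit in ((-1, bounds[idx][0]), (1, bounds[idx][1])):
        step = 0.05
        v, prev = theta_hat[idx], theta_hat[idx]
        bracket = None
        for _ in range(60):
            prev = v
            v = v + direction * step
            v = max(min(v, bounds[idx][1]), bounds[idx][0])
            if profile_nll(v) > target:
                bracket = (min(prev, v), max(prev, v))
                break
            if v == limit:
                break
            step *= 1.5
        if bracket is None:
            ends.append(limit)
        else:
            try:
                ends.append(brentq(lambda u: profile_nll(u) - target, *bracket, xtol=1e-4))
            except ValueError:
                ends.append(limit)
    return (float(min(ends[0], theta_hat[idx])), float(max(ends[1], theta_hat[idx])))


def orient_alpha(fit: GenomicClineFit, cfg: ZoneConfig, species1: str) -> GenomicClineFit:
    """Orient alpha so that positive values mean excess ancestry from the
    more MHC-diverse species.

    ``species1`` names the species whose ancestry proportion pbar/pMHC
    measures.  Relabeling species maps (alpha, beta) -> (-alpha, beta), so
    when species 1 is the less diverse one, alpha and its interval flip.
    beta is invariant under the relabeling.
    """
    if species1 not in cfg.species_pair:
        raise ValueError(f"species1 {species1!r} not in configured pair {cfg.species_pair}")
    if species1 == cfg.more_diverse_species:
        return replace(fit, oriented_to_more_diverse=True)
    intervals = dict(fit.support_intervals)
    if "alpha" in intervals:
        lo, hi = intervals["alpha"]
        intervals["alpha"] = (-hi, -lo)
    return replace(
        fit, alpha=-fit.alpha, support_intervals=intervals, oriented_to_more_diverse=True
    )
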