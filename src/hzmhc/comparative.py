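"""Phylogenetic GLS synthesis across hybrid zones.

The unit of observation is a hybridizing species *pair* (one row per pair
per MHC class).  Residual correlation between pairs is derived from a
time-calibrated tree: each pair maps to the node of its most recent common
ancestor, the cophenetic (path-length) distance d between two such nodes is
normalized by the largest tip-to-tip distance on the tree, and

    corr = 1 - d / d_max,

so pairs whose ancestors coincide correlate perfectly and pairs whose
ancestors sit at opposite ends of the tree are independent.  Pagel's lambda
scales the off-diagonal correlations and is estimated by profile maximum
likelihood on [0, 1].  Observations of different MHC classes are assumed
phylogenetically uncorrelated (block-diagonal structure), and known
estimation variances enter as inverse-variance weights (omitted for
permutation-based SES responses, whose variance is ~1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "PairCorrelationMatrix",
    "PGLSFit",
    "pair_correlation_matrix",
    "apply_lambda",
    "pgls_fit",
    "lrt",
    "aggregate_transects",
]


@dataclass
class PairCorrelationMatrix:
    pair_ids: list[tuple[str, str]]
    matrix: np.ndarray
    lambda_applied: float = 1.0
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.pair_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match number of pairs")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
    return depths


def pair_correlation_matrix(
    tree: dendropy.Tree | str,
    pairs: list[tuple[str, str]],
    repair_psd: bool = True,
) -> PairCorrelationMatrix:
    """Expected correlation matrix between species pairs from a tree.

    ``tree`` may be a dendropy Tree or a Newick string/path.  Each pair's
    node is the MRCA of its two species; corr_ij = 1 - d_ij / d_max with
    d_ij the path length between nodes i and j and d_max the largest
    cophenetic distance between any two tips.  1 - d/d_max is not
    guaranteed positive semidefinite, so negative eigenvalues are clipped
    and the diagonal renormalized when ``repair_psd``.
    """
    if isinstance(tree, str):
        import os

        src = {"path": tree} if os.path.exists(tree) else {"data": tree}
        tree = dendropy.Tree.get(**src, schema="newick")
    tree.is_rooted = True  # time-calibrated trees are rooted; MRCAs need a root
    labels = {t.label for t in tree.taxon_namespace}
    missing = [s for p in pairs for s in p if s not in labels]
    if missing:
        raise ValueError(f"species missing from tree: {sorted(set(missing))}")
    depths = _node_depths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    d_max = max(
        pdm.patristic_distance(t1, t2) for i, t1 in enumerate(taxa) for t2 in taxa[i + 1 :]
    )
    mrcas = [tree.mrca(taxon_labels=list(p)) for p in pairs]
    n = len(pairs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            # MRCA of two internal nodes = MRCA of the union of their tip sets
            anc = tree.mrca(taxon_labels=sorted(set(pairs[i]) | set(pairs[j])))
            d = depths[mrcas[i]] + depths[mrcas[j]] - 2.0 * depths[anc]
            mat[i, j] = mat[j, i] = 1.0 - d / d_max
    repaired = False
    if repair_psd:
        eigval, eigvec = np.linalg.eigh(mat)
        if eigval.min() < -1e-10:
            eigval = np.clip(eigval, 0.0, None)
            mat = eigvec @ np.diag(eigval) @ eigvec.T
            d = np.sqrt(np.diag(mat))
            mat = mat / np.outer(d, d)
            repaired = True
    return PairCorrelationMatrix(list(pairs), mat, 1.0, repaired)


def apply_lambda(corr: PairCorrelationMatrix, lam: float) -> PairCorrelationMatrix:
    """Pagel's lambda transform: off-diagonals scaled by lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda outside [0, 1]")
    mat = lam * corr.matrix + (1.0 - lam) * np.eye(len(corr.pair_ids))
    return PairCorrelationMatrix(corr.pair_ids, mat, corr.lambda_applied * lam, corr.psd_repaired)


@dataclass
class PGLSFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    lambda_: float
    log_likelihood: float
    sigma2: float
    n_obs: int
    n_params: int  # count used for information criteria / LRT df
    weights_used: bool
    terms: tuple[str, ...] = ()


def _design_matrix(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    classes = sorted(data["mhc_class"].unique())
    class_dummy = None
    if "class" in terms and len(classes) > 1:
        class_dummy = (data["mhc_class"] == classes[1]).to_numpy(dtype=float)
        cols.append(class_dummy)
        names.append(f"class[{classes[1]}]")
    if "time" in terms:
        cols.append(data["time"].to_numpy(dtype=float))
        names.append("time")
    if "class:time" in terms:
        if class_dummy is None or "time" not in terms:
            raise ValueError("class:time interaction requires both main effects")
        cols.append(class_dummy * data["time"].to_numpy(dtype=float))
        names.append(f"class[{classes[1]}]:time")
    return np.column_stack(cols), names


def _block_correlation(data: pd.DataFrame, corr: PairCorrelationMatrix) -> np.ndarray:
    """Row correlation: phylogenetic within an MHC class, zero across."""
    pair_index = {p: i for i, p in enumerate(corr.pair_ids)}
    try:
        rows = [pair_index[p] for p in data["pair"]]
    except KeyError as e:
        raise ValueError(f"pair {e.args[0]} not in correlation matrix") from None
    base = corr.matrix[np.ix_(rows, rows)]
    same_class = (
        data["mhc_class"].to_numpy()[:, None] == data["mhc_class"].to_numpy()[None, :]
    )
    out = np.where(same_class, base, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def _fit_gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    n, k = X.shape
    L = np.linalg.cholesky(V)
    from scipy.linalg import solve_triangular

    yt = solve_triangular(L, y, lower=True)
    Xt = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-10)  # ML variance, floored for near-perfect fits
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    xtx_inv = np.linalg.inv(Xt.T @ Xt)
    sigma2_unb = rss / max(n - k, 1)
    bse = np.sqrt(sigma2_unb * np.diag(xtx_inv))
    return beta, bse, sigma2, ll


def pgls_fit(
    data: pd.DataFrame,
    corr: PairCorrelationMatrix,
    terms: list[str] = ("class",),
    weights: str | None = "inverse_variance",
    lam: float | str = "ml",
) -> PGLSFit:
    """GLS with phylogenetic pair correlation, Pagel's lambda and optional
    inverse-variance weights.

    ``data`` columns: pair (tuple), mhc_class, response; variance when
    weighted; time when a time term is requested.  ``lam='ml'`` profiles
    lambda over a 101-point grid on [0, 1] with bounded local refinement;
    a float fixes it.  Residual covariance is
    sigma^2 * W^{-1/2} C(lambda) W^{-1/2} with W the weight matrix.
    """
    terms = list(terms)
    data = data.reset_index(drop=True)
    y = data["response"].to_numpy(dtype=float)
    X, names = _design_matrix(data, terms)
    C0 = _block_correlation(data, corr)
    n = len(y)
    if weights == "inverse_variance":
        if "variance" not in data.columns:
            raise ValueError("inverse-variance weights need a 'variance' column")
        w = 1.0 / data["variance"].to_numpy(dtype=float)
    elif weights is None:
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weights spec {weights!r}")
    sqrt_w = np.sqrt(w)
    I = np.eye(n)

    def ll_at(lam_val: float) -> tuple:
        C = lam_val * C0 + (1 - lam_val) * I
        V = C / np.outer(sqrt_w, sqrt_w)
        return _fit_gls(y, X, V)

    if lam == "ml":
        grid = np.linspace(0.0, 1.0, 101)
        lls = np.array([ll_at(g)[3] for g in grid])
        k_best = int(np.argmax(lls))
        lo, hi = grid[max(k_best - 1, 0)], grid[min(k_best + 1, 100)]
        res = minimize_scalar(lambda g: -ll_at(g)[3], bounds=(lo, hi), method="bounded")
        lam_hat = float(res.x) if -res.fun >= lls[k_best] else float(grid[k_best])
        lambda_estimated = True
    else:
        lam_hat = float(lam)
        if not (0.0 <= lam_hat <= 1.0):
            raise ValueError("lambda outside [0, 1]")
        lambda_estimated = False

    beta, bse, sigma2, ll = ll_at(lam_hat)
    k = X.shape[1]
    df_resid = max(n - k, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    n_params = k + 1 + (1 if lambda_estimated else 0)  # + sigma^2 (+ lambda)
    return PGLSFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        lambda_=round(lam_hat, 4),
        log_likelihood=float(ll),
        sigma2=float(sigma2),
        n_obs=n,
        n_params=n_params,
        weights_used=weights == "inverse_variance",
        terms=tuple(terms),
    )


def lrt(full: PGLSFit, reduced: PGLSFit) -> float:
    """Likelihood-ratio test of nested PGLS models: chi-square on
    2 * delta-logL with df = parameter-count difference."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted to different data")
    df = full.n_params - reduced.n_params
    if df < 0 or not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced must be a sub-model of full)")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    # profiled lambda makes logL accurate only to optimizer tolerance
    if stat < -1e-4:
        raise ValueError("full model has lower likelihood than reduced: fit pathology")
    stat = max(stat, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def aggregate_transects(
    estimates: pd.DataFrame, group_cols: list[str] = ("pair", "mhc_class")
) -> pd.DataFrame:
    """Average estimates and their variances over replicate transects of the
    same species pair (plain arithmetic means of both)."""
    required = set(group_cols) | {"response"}
    if not required.issubset(estimates.columns):
        raise ValueError(f"need columns {sorted(required)}")
    agg = {"response": "mean"}
    if "variance" in estimates.columns:
        agg["variance"] = "mean"
    out = estimates.groupby(list(group_cols), sort=False).agg(agg).reset_index()
    return out
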