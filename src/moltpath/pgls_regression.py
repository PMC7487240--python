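"""Phylogenetic generalized least squares and AICc-ranked model sets.

The regression ``y = X b + e`` has residual covariance ``sigma^2 V`` with
``V`` derived from the tree: pure Brownian motion (``V = C``, the default),
a fixed Pagel's lambda deformation, or lambda estimated by ML jointly with
the coefficients.  Everything is computed in the whitened space ``L^{-1} y``,
``L^{-1} X`` with ``V = L L'``, so a star tree (or lambda = 0) reproduces
ordinary least squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .evomodel_continuous import aicc, aicc_weights
from .treekit import Phylogeny, lambda_max, transform_lambda, vcv_matrix

__all__ = ["PGLSResult", "pgls_fit", "rank_model_set"]


@dataclass
class PGLSResult:
    response: str
    predictors: list
    beta: np.ndarray          # intercept first
    se: np.ndarray
    t: np.ndarray
    p_coef: np.ndarray        # two-sided
    F: float
    df1: int
    df2: int
    p_model: float
    r2: float
    adj_r2: float
    lnL: float
    k: int
    n: int
    aicc: float
    correlation: str          # "BM", "lambda=0.73", ...
    lam: float | None = None
    meta: dict = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        names = ["(intercept)"] + list(self.predictors)
        return pd.DataFrame({"beta": self.beta, "se": self.se,
                             "t": self.t, "p": self.p_coef}, index=names)


def _design(y, X, predictors):
    if isinstance(X, pd.DataFrame):
        predictors = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] == len(y):
            X = X.T
        if predictors is None:
            predictors = [f"x{i}" for i in range(X.shape[1])]
    return X, list(predictors)


def _whitened_stats(V, y, Xd):
    n, p1 = Xd.shape
    L = cholesky(V, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, Xd, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # GLS intercept-only null under the same V
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw / (ones_w @ ones_w))
    rss0 = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    s2_ml = rss / n
    lnL = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    return beta, rss, rss0, XtX, lnL


def pgls_fit(tree: Phylogeny, y, X, correlation: str = "BM",
             lam: float | None = None, response: str = "y",
             predictors: list | None = None) -> PGLSResult:
    """Fit a PGLS regression.

    ``correlation`` is ``"BM"`` (lambda fixed at 1), ``"lambda-fixed"``
    (supply ``lam``) or ``"lambda-ML"`` (lambda profiled by ML; counts one
    extra parameter in AICc).
    """
    if isinstance(y, (pd.Series, dict)):
        y = np.asarray([y[t] for t in tree.tip_labels], dtype=float)
    y = np.asarray(y, dtype=float)
    n = tree.n_tips
    if len(y) != n:
        raise ValueError("response length does not match the tree's tip count")
    if isinstance(X, pd.DataFrame):
        missing = [t for t in tree.tip_labels if t not in X.index]
        if not missing and list(X.index) != list(tree.tip_labels):
            X = X.loc[tree.tip_labels]
        elif missing:
            raise ValueError(f"species missing from predictor table: {missing}")
    X, predictors = _design(y, X, predictors)
    p = X.shape[1]
    if n <= p + 2:
        raise ValueError(f"n={n} too small for {p} predictors")
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError(f"design matrix is rank deficient; predictors {predictors}")
    C = vcv_matrix(tree)

    est_lambda = correlation == "lambda-ML"
    if correlation == "BM":
        V = C.matrix
        lam_used = 1.0
        corr_label = "BM"
    elif correlation == "lambda-fixed":
        if lam is None:
            raise ValueError("lambda-fixed requires lam")
        V = transform_lambda(C, lam).matrix
        lam_used = float(lam)
        corr_label = f"lambda={lam_used:g}"
    elif est_lambda:
        lmax = lambda_max(C.matrix)

        def obj(l):
            Vl = transform_lambda(C, l).matrix
            return -_whitened_stats(Vl, y, Xd)[4]

        res = minimize_scalar(obj, bounds=(0.0, lmax), method="bounded",
                              options={"xatol": 1e-6})
        lam_used = float(res.x)
        V = transform_lambda(C, lam_used).matrix
        corr_label = f"lambda-ML={lam_used:.4g}"
    else:
        raise ValueError(f"unknown correlation mode {correlation!r}")

    beta, rss, rss0, XtX, lnL = _whitened_stats(V, y, Xd)
    df1, df2 = p, n - p - 1
    s2 = rss / df2
    cov_beta = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    p_coef = 2 * t_dist.sf(np.abs(tvals), df2)
    F = ((rss0 - rss) / df1) / (rss / df2) if df1 > 0 else np.nan
    p_model = float(f_dist.sf(F, df1, df2)) if df1 > 0 else np.nan
    r2 = 1.0 - rss / rss0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    k = p + 2 + (1 if est_lambda else 0)  # coefficients + intercept + sigma^2 (+ lambda)
    return PGLSResult(response, predictors, beta, se, tvals, p_coef,
                      float(F), df1, df2, p_model, float(r2), float(adj_r2),
                      lnL, k, n, aicc(lnL, k, n), corr_label, lam_used)


def rank_model_set(tree: Phylogeny, data: pd.DataFrame, response: str,
                   model_specs: list, correlation: str = "BM") -> pd.DataFrame:
    """Fit a set of candidate predictor subsets and rank them by AICc.

    ``model_specs`` is a list of predictor-name lists.  The returned table
    carries adjusted R-squared, the model p-value, AICc, delta AICc and the
    Akaike weight, sorted ascending by AICc (ties keep input order).
    """
    missing = [t for t in tree.tip_labels if t not in data.index]
    if missing:
        raise ValueError(f"species missing from data table: {missing}")
    data = data.loc[tree.tip_labels]
    y = data[response].to_numpy(dtype=float)
    rows = []
    for i, spec in enumerate(model_specs):
        fit = pgls_fit(tree, y, data[list(spec)], correlation=correlation,
                       response=response, predictors=list(spec))
        rows.append({"response": response, "model": " + ".join(spec),
                     "order": i, "adj_r2": fit.adj_r2, "p": fit.p_model,
                     "aicc": fit.aicc, "lnL": fit.lnL, "k": fit.k,
                     "correlation": fit.correlation})
    table = pd.DataFrame(rows)
    w = aicc_weights(table["aicc"].to_numpy())
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["aicc_weight"] = w
    table = table.sort_values(["aicc", "order"], kind="stable").drop(columns="order")
    return table.reset_index(drop=True)
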