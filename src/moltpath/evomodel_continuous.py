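"""Maximum-likelihood Gaussian trait models on trees: BM, OU, EB, Pagel's lambda.

Each model implies a tip covariance ``sigma^2 * V(theta)`` with ``V`` from
:mod:`moltpath.treekit`.  For any fixed structural parameter ``theta`` (OU
``alpha``, EB ``r``, lambda), the root state ``z0`` and the rate ``sigma^2``
have closed-form GLS/ML solutions, so fitting reduces to a bounded 1-D search
over ``theta``.  The ML (not REML) variance denominator ``n`` is used
throughout so that AICc comparisons are consistent across models.

Presence/absence (0/1) characters may be passed to these fits; this mirrors
common practice of reporting Gaussian-model AICc weights for binary
presence variables, and the resulting fit carries a ``binary_trait`` flag in
its metadata so downstream tables can disclose it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .treekit import (
    Phylogeny,
    PhyloCovariance,
    lambda_max,
    transform_eb,
    transform_lambda,
    transform_ou,
    vcv_matrix,
)

__all__ = [
    "ContinuousFit",
    "gaussian_phylo_loglik",
    "fit_model",
    "aicc",
    "aicc_weights",
    "weighted_rate_summary",
    "phylo_signal_lambda",
    "asr_continuous",
]

_PARAM_COUNT = {"BM": 2, "OU": 3, "EB": 3, "lambda": 3}


@dataclass
class ContinuousFit:
    model: str
    sigma2: float
    z0: float
    lnL: float
    k: int
    n: int
    aicc: float
    alpha: float | None = None   # OU pull, 1/time
    r: float | None = None       # EB decay, 1/time, <= 0
    lam: float | None = None     # Pagel's lambda
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        """The rate parameter used in weighted-rate summaries (sigma^2)."""
        return self.sigma2


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(values) -> np.ndarray:
    """Akaike weights ``w_i = exp(-D_i/2) / sum_j exp(-D_j/2)`` with
    ``D_i = AICc_i - min AICc``.  Invariant to adding a constant."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one AICc value")
    if np.any(np.isnan(v)):
        bad = np.flatnonzero(np.isnan(v)).tolist()
        raise ValueError(f"NaN AICc at positions {bad}")
    d = v - np.nanmin(v)
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------

def _chol(V: np.ndarray):
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance matrix is singular; repair PSD structure "
            "(e.g. collapse zero-length cherries) before fitting"
        ) from exc


def gaussian_phylo_loglik(C: PhyloCovariance, x, sigma2: float, z0: float) -> float:
    """Log density of tip values under ``Normal(z0 * 1, sigma2 * C)``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    V = sigma2 * C.matrix
    cf = _chol(V)
    r = x - z0
    quad = r @ cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _profile_loglik(V: np.ndarray, x: np.ndarray):
    """Profile z0 and sigma^2 out of the Gaussian likelihood for structure V.

    Returns (lnL, sigma2_hat, z0_hat).
    """
    n = len(x)
    cf = _chol(V)
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    z0 = float(Vi1 @ x / (Vi1 @ ones))
    r = x - z0
    s2 = float(r @ cho_solve(cf, r) / n)
    if s2 <= 0:
        return -np.inf, 0.0, z0
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
    return lnL, s2, z0


def _optimize_structural(objective_raw, lo: float, hi: float, n_starts: int = 6):
    """Bounded 1-D maximization: deterministic grid of starts refined by
    Brent's method on bracketing subintervals.  Parameter values where the
    covariance degenerates (e.g. lambda at the PSD boundary) score -inf."""

    def objective(t):
        try:
            return objective_raw(t)
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf

    grid = np.linspace(lo, hi, max(n_starts, 3))
    vals = [objective(g) for g in grid]
    best_i = int(np.argmax(vals))
    a = grid[max(best_i - 1, 0)]
    b = grid[min(best_i + 1, len(grid) - 1)]
    if a == b:
        return grid[best_i], vals[best_i]
    res = minimize_scalar(lambda t: -objective(t), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-6 * max(abs(hi - lo), 1.0)})
    cand = [(grid[best_i], vals[best_i]), (float(res.x), -float(res.fun))]
    return max(cand, key=lambda p: p[1])


def fit_model(tree: Phylogeny, x, model: str = "BM",
              alpha_max: float | None = None, r_min: float | None = None) -> ContinuousFit:
    """Fit one Gaussian trait model by ML.

    Parameters
    ----------
    tree : Phylogeny
    x : array-like or mapping
        Tip values; if a mapping, keyed by tip label.
    model : {"BM", "OU", "EB", "lambda"}
    alpha_max, r_min : optional structural-parameter bounds.  Defaults are
        ``50 / depth`` for the OU pull and ``-10 / depth`` for the EB decay.
    """
    if isinstance(x, dict):
        x = np.array([x[t] for t in tree.tip_labels], dtype=float)
    x = np.asarray(x, dtype=float)
    n = tree.n_tips
    if n < 4:
        raise ValueError("model fitting requires at least 4 tips")
    if len(x) != n:
        raise ValueError("trait length does not match tip count")
    if np.ptp(x) == 0:
        raise ValueError("invariant character: trait has zero variance")
    k = _PARAM_COUNT[model]
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for this n and parameter count")
    C = vcv_matrix(tree)
    depth = float(np.diag(C.matrix).max())
    meta = {"binary_trait": bool(set(np.unique(x)) <= {0.0, 1.0})}

    if model == "BM":
        lnL, s2, z0 = _profile_loglik(C.matrix, x)
        return ContinuousFit("BM", s2, z0, lnL, k, n, aicc(lnL, k, n), meta=meta)

    if model == "OU":
        hi = alpha_max if alpha_max is not None else 50.0 / depth

        def obj(a):
            V = transform_ou(C, a).matrix
            return _profile_loglik(V, x)[0]

        ahat, lnL = _optimize_structural(obj, 0.0, hi, n_starts=8)
        V = transform_ou(C, ahat).matrix
        lnL, s2, z0 = _profile_loglik(V, x)
        return ContinuousFit("OU", s2, z0, lnL, k, n, aicc(lnL, k, n),
                             alpha=float(ahat), meta=meta)

    if model == "EB":
        lo = r_min if r_min is not None else -10.0 / depth

        def obj(r):
            V = transform_eb(tree, r).matrix
            return _profile_loglik(V, x)[0]

        rhat, lnL = _optimize_structural(obj, lo, 0.0)
        V = transform_eb(tree, rhat).matrix
        lnL, s2, z0 = _profile_loglik(V, x)
        return ContinuousFit("EB", s2, z0, lnL, k, n, aicc(lnL, k, n),
                             r=float(rhat), meta=meta)

    if model == "lambda":
        lmax = lambda_max(C.matrix)

        def obj(lam):
            V = transform_lambda(C, lam).matrix
            return _profile_loglik(V, x)[0]

        lhat, lnL = _optimize_structural(obj, 0.0, lmax)
        V = transform_lambda(C, lhat).matrix
        lnL, s2, z0 = _profile_loglik(V, x)
        return ContinuousFit("lambda", s2, z0, lnL, k, n, aicc(lnL, k, n),
                             lam=float(lhat), meta=meta)

    raise ValueError(f"unknown model {model!r}")


def phylo_signal_lambda(tree: Phylogeny, x) -> dict:
    """Pagel's lambda as a measure of phylogenetic signal.

    Returns the ML estimate together with the log-likelihood profile at the
    optimum and at the star (0) and BM (1) endpoints.
    """
    fit = fit_model(tree, x, "lambda")
    if isinstance(x, dict):
        x = np.array([x[t] for t in tree.tip_labels], dtype=float)
    C = vcv_matrix(tree)
    lnL0 = _profile_loglik(transform_lambda(C, 0.0).matrix, np.asarray(x, float))[0]
    lnL1 = _profile_loglik(C.matrix, np.asarray(x, float))[0]
    return {"lambda": fit.lam, "lnL": fit.lnL, "lnL_0": lnL0, "lnL_1": lnL1,
            "fit": fit}


def weighted_rate_summary(fits_by_region: dict) -> dict:
    """AICc-weighted rate totals across feather regions.

    ``fits_by_region`` maps region name -> {model name -> ContinuousFit}; each
    region must carry the same model set.  Within each region the AICc weights
    across models multiply that model's rate (sigma^2); the weighted rates are
    then summed across regions per model.
    """
    regions = list(fits_by_region)
    if not regions:
        raise ValueError("no regions supplied")
    models = sorted(fits_by_region[regions[0]])
    totals = {m: 0.0 for m in models}
    for region in regions:
        fits = fits_by_region[region]
        missing = [m for m in models if m not in fits]
        if missing or set(fits) != set(models):
            raise ValueError(f"region {region!r} missing models {missing}")
        w = aicc_weights([fits[m].aicc for m in models])
        for m, wi in zip(models, w):
            totals[m] += wi * fits[m].rate
    return totals


# ---------------------------------------------------------------------------
# Continuous ancestral states (GLS under BM)
# ---------------------------------------------------------------------------

def _full_mrca_depths(tree: Phylogeny) -> np.ndarray:
    """(n_nodes, n_nodes) matrix of MRCA depths between all node pairs."""
    depths = tree.depths()
    anc = []
    for i in range(tree.n_nodes):
        path = []
        j = i
        while j != -1:
            path.append(j)
            j = int(tree.parent[j])
        anc.append(path[::-1])  # root .. node
    n = tree.n_nodes
    M = np.zeros((n, n))
    for i in range(n):
        ai = anc[i]
        seti = {node: k for k, node in enumerate(ai)}
        for j in range(i, n):
            mrca = next(node for node in reversed(anc[j]) if node in seti)
            M[i, j] = M[j, i] = depths[mrca]
    return M


def asr_continuous(tree: Phylogeny, x) -> dict:
    """BM ancestral state estimates: conditional mean/variance of internal
    node states given the tips, with the root pinned to the GLS estimate of
    ``z0`` (the root estimate equals the BM fit's ``z0``)."""
    if isinstance(x, dict):
        x = np.array([x[t] for t in tree.tip_labels], dtype=float)
    x = np.asarray(x, dtype=float)
    fit = fit_model(tree, x, "BM")
    M = _full_mrca_depths(tree)
    tips = np.arange(tree.n_tips)
    internals = np.arange(tree.n_tips, tree.n_nodes)
    Ctt = M[np.ix_(tips, tips)]
    Cnt = M[np.ix_(internals, tips)]
    Cnn = M[np.ix_(internals, internals)]
    cf = _chol(Ctt)
    W = cho_solve(cf, Cnt.T)          # Ctt^{-1} Cnt'
    mean = fit.z0 + Cnt @ cho_solve(cf, x - fit.z0)
    var = fit.sigma2 * (np.diag(Cnn) - np.einsum("ij,ji->i", Cnt, W))
    labels = [tree.node_labels[i] if tree.node_labels else f"node{i}" for i in internals]
    return {
        "node_index": internals,
        "node_label": labels,
        "estimate": mean,
        "variance": np.maximum(var, 0.0),
        "fit": fit,
    }
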