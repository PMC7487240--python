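"""Simulation-based phylogenetic ANOVA with Holm correction across regions.

The observed statistic is the ordinary one-way ANOVA F comparing a continuous
variable (e.g. migration distance) between groups defined by a discrete trait
(e.g. presence of prealternate molt in a feather region).  Because species are
phylogenetically non-independent, the null distribution of F is obtained by
simulating the continuous variable under Brownian motion on the tree (rate
and root estimated from the data) and recomputing F against the fixed group
labels; the p-value uses the add-one estimator so it can never be exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky

from .evomodel_continuous import fit_model
from .treekit import Phylogeny, vcv_matrix

__all__ = ["PhyloANOVAResult", "anova_f", "phylo_anova", "holm_adjust"]


@dataclass
class PhyloANOVAResult:
    name: str
    F: float
    p: float
    n_sim: int
    seed: int
    degenerate: bool = False
    adjusted_p: float | None = None


def anova_f(y: np.ndarray, groups: np.ndarray):
    """One-way ANOVA F statistic; returns (F, degenerate) where degenerate
    flags zero within-group variance (F is infinite)."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n = len(y)
    grand = y.mean()
    ss_between = sum(len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2
                     for g in labels)
    ss_within = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                    for g in labels)
    df1, df2 = len(labels) - 1, n - len(labels)
    if ss_within == 0:
        return np.inf, True
    return (ss_between / df1) / (ss_within / df2), False


def _batch_f(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way F over rows of Y (n_sim x n)."""
    labels = np.unique(groups)
    n = Y.shape[1]
    grand = Y.mean(axis=1, keepdims=True)
    ssb = np.zeros(Y.shape[0])
    ssw = np.zeros(Y.shape[0])
    for g in labels:
        sel = Y[:, groups == g]
        mu = sel.mean(axis=1, keepdims=True)
        ssb += sel.shape[1] * (mu[:, 0] - grand[:, 0]) ** 2
        ssw += ((sel - mu) ** 2).sum(axis=1)
    df1, df2 = len(labels) - 1, n - len(labels)
    with np.errstate(divide="ignore"):
        return (ssb / df1) / (ssw / df2)


def phylo_anova(tree: Phylogeny, y, groups, n_sim: int = 1000, seed: int = 0,
                name: str = "trait") -> PhyloANOVAResult:
    """Phylogenetic ANOVA of ``y`` across ``groups`` on ``tree``."""
    if isinstance(y, dict):
        y = [y[t] for t in tree.tip_labels]
    if isinstance(groups, dict):
        groups = [groups[t] for t in tree.tip_labels]
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")

    f_obs, degenerate = anova_f(y, groups)
    fit = fit_model(tree, y, "BM")
    C = vcv_matrix(tree).matrix
    L = cholesky(fit.sigma2 * C, lower=True)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, tree.n_tips))
    Y = fit.z0 + Z @ L.T
    f_sim = _batch_f(Y, groups)
    p = (1 + np.sum(f_sim >= f_obs)) / (1 + n_sim)
    return PhyloANOVAResult(name, float(f_obs), float(p), n_sim, seed, degenerate)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm's sequential Bonferroni: sort ascending, adjust the i-th smallest
    by ``(m - i + 1) p_(i)``, enforce monotonicity by a running maximum, cap
    at 1, and return in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj
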