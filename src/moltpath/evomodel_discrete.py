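"""Mk models for discrete characters: likelihoods, ER/ARD fits, marginal
ancestral states, the Pagel correlated-evolution test, and transition counts.

The continuous-time Markov chain has instantaneous rate matrix ``Q`` (rows sum
to zero) and branch transition matrices ``P(t) = expm(Q t)``.  Tip likelihoods
propagate rootward by Felsenstein pruning; the root is integrated against a
root prior (flat by default).  For two-state chains ``P(t)`` has a closed
form; larger chains use an eigendecomposition when ``Q`` is diagonalizable
with a well-conditioned eigenbasis and fall back to scaling-and-squaring
(``scipy.linalg.expm``) otherwise, so defective ARD matrices remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .treekit import Phylogeny

__all__ = [
    "MkFit",
    "ASRResult",
    "mk_loglik",
    "fit_mk",
    "lrt",
    "marginal_asr",
    "pagel_dependence_test",
    "count_transitions",
    "build_er_q",
    "build_ard_q",
]

_RATE_LO, _RATE_HI = 1e-9, 1e4


@dataclass
class MkFit:
    states: list
    Q: np.ndarray
    model: str
    lnL: float
    k: int
    n: int
    aic: float
    aicc: float
    root_prior: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ASRResult:
    node_index: np.ndarray
    node_label: list
    probabilities: np.ndarray   # (n_internal, n_states)
    states: list

    @property
    def map_states(self) -> np.ndarray:
        """MAP state per node; ties broken toward the lowest state index
        (absence), which is the conservative choice for gain counting."""
        return np.argmax(self.probabilities, axis=1)

    def tie_flags(self, tol: float = 1e-9) -> np.ndarray:
        p = np.sort(self.probabilities, axis=1)
        return (p[:, -1] - p[:, -2]) < tol


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------

def build_er_q(m: int, rate: float) -> np.ndarray:
    Q = np.full((m, m), rate)
    np.fill_diagonal(Q, -(m - 1) * rate)
    return Q


def build_ard_q(m: int, rates) -> np.ndarray:
    """Off-diagonal rates in row-major order (skipping the diagonal)."""
    rates = np.asarray(rates, dtype=float)
    Q = np.zeros((m, m))
    it = iter(rates)
    for i in range(m):
        for j in range(m):
            if i != j:
                Q[i, j] = next(it)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _validate_q(Q: np.ndarray) -> None:
    Q = np.asarray(Q, float)
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-10 * max(1.0, np.abs(Q).max())):
        raise ValueError("Q rows must sum to zero")


def branch_transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``P(t) = expm(Q t)`` for every branch length, vectorized over branches."""
    Q = np.asarray(Q, float)
    lengths = np.asarray(lengths, float)
    m = Q.shape[0]
    if m == 2:
        # closed form: P(t) = pi + exp(-s t) (I - pi), s = a + b
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        if s == 0:
            return np.broadcast_to(np.eye(2), (len(lengths), 2, 2)).copy()
        pi = np.array([[b, a], [b, a]]) / s
        decay = np.exp(-s * lengths)[:, None, None]
        return pi[None] + decay * (np.eye(2) - pi)[None]
    # general case: eigendecomposition when safe, expm fallback
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e8:
            E = np.exp(np.multiply.outer(lengths, w))
            P = np.einsum("ij,tj,jk->tik", U, E, Uinv).real
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    return np.array([expm(Q * t) for t in lengths])


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _tip_partials(tree: Phylogeny, states, state_list) -> np.ndarray:
    if isinstance(states, dict):
        states = [states[t] for t in tree.tip_labels]
    states = list(states)
    m = len(state_list)
    index = {s: i for i, s in enumerate(state_list)}
    part = np.zeros((tree.n_tips, m))
    for i, s in enumerate(states):
        if s is None or (isinstance(s, float) and np.isnan(s)):
            part[i] = 1.0  # missing: sums over states
        else:
            if s not in index:
                raise ValueError(f"tip state {s!r} not in model state set {state_list}")
            part[i, index[s]] = 1.0
    return part


def _down_pass(tree: Phylogeny, tip_part: np.ndarray, P: np.ndarray):
    """Partial likelihoods of the data below each node, with per-node log
    scaling factors to avoid underflow.  Returns (partials, log_scale)."""
    m = tip_part.shape[1]
    down = np.zeros((tree.n_nodes, m))
    logsc = np.zeros(tree.n_nodes)
    down[: tree.n_tips] = tip_part
    for node in tree.postorder():
        if node < tree.n_tips:
            continue
        acc = np.ones(m)
        ls = 0.0
        for c in tree.children[node]:
            acc = acc * (P[c] @ down[c])
            ls += logsc[c]
        mx = acc.max()
        if mx <= 0:
            raise ValueError("zero likelihood encountered during pruning")
        down[node] = acc / mx
        logsc[node] = ls + np.log(mx)
    return down, logsc


def mk_loglik(tree: Phylogeny, states, Q: np.ndarray, root_prior=None) -> float:
    """Felsenstein-pruning log-likelihood of discrete tip data under ``Q``."""
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    _validate_q(Q)
    m = Q.shape[0]
    state_list = list(range(m))
    prior = np.full(m, 1.0 / m) if root_prior is None else np.asarray(root_prior, float)
    tip_part = _tip_partials(tree, states, state_list)
    P = branch_transition_matrices(Q, tree.blen)
    down, logsc = _down_pass(tree, tip_part, P)
    root = tree.root
    L = prior @ down[root]
    return float(np.log(L) + logsc[root])


# ---------------------------------------------------------------------------
# Fitting and tests
# ---------------------------------------------------------------------------

def _observed_states(tree, states):
    if isinstance(states, dict):
        states = [states[t] for t in tree.tip_labels]
    arr = [int(s) for s in states]
    return arr, sorted(set(arr))


def fit_mk(tree: Phylogeny, states, model: str = "ER", root_prior=None,
           n_states: int | None = None) -> MkFit:
    """ML fit of an equal-rates or all-rates-different Mk model.

    Rates are optimized on the log scale with a deterministic multi-start
    (grid of starting rates spanning four orders of magnitude around one
    expected change per tree depth).
    """
    arr, observed = _observed_states(tree, states)
    if len(observed) < 2:
        raise ValueError("invariant character: cannot fit an Mk model")
    m = n_states or (max(observed) + 1)
    n = tree.n_tips
    prior = np.full(m, 1.0 / m) if root_prior is None else np.asarray(root_prior, float)
    depth = tree.depth()
    n_rates = 1 if model == "ER" else m * (m - 1)

    def build(logr):
        r = np.exp(logr)
        return build_er_q(m, r[0]) if model == "ER" else build_ard_q(m, r)

    def nll(logr):
        try:
            return -mk_loglik(tree, arr, build(logr), prior)
        except (ValueError, FloatingPointError):
            return 1e10

    best = None
    for scale in (0.1, 1.0, 10.0):
        x0 = np.full(n_rates, np.log(scale / depth))
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(_RATE_LO), np.log(_RATE_HI))] * n_rates)
        if best is None or res.fun < best.fun:
            best = res
    Q = build(best.x)
    lnL = -float(best.fun)
    k = n_rates
    aic = -2 * lnL + 2 * k
    aicc_val = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else np.nan
    return MkFit(list(range(m)), Q, model, lnL, k, n, aic, aicc_val, prior)


def lrt(lnL_simple: float, lnL_complex: float, df: int, tol: float = 1e-6) -> dict:
    """Likelihood-ratio test of nested models via the chi-square upper tail."""
    stat = 2.0 * (lnL_complex - lnL_simple)
    if stat < -tol:
        raise ValueError(
            f"complex model has lower likelihood (stat={stat:.4g}); optimizer failure?")
    stat = max(stat, 0.0)
    return {"statistic": stat, "df": df, "p": float(chi2.sf(stat, df))}


def marginal_asr(tree: Phylogeny, states, Q: np.ndarray, root_prior=None) -> ASRResult:
    """Marginal ancestral state probabilities at every internal node.

    Computed by combining the rootward ("down") partial likelihoods with an
    "up" message carrying the likelihood of all data outside each node's
    subtree -- algebraically identical to re-rooting at each node.
    """
    _validate_q(Q)
    m = Q.shape[0]
    prior = np.full(m, 1.0 / m) if root_prior is None else np.asarray(root_prior, float)
    tip_part = _tip_partials(tree, states, list(range(m)))
    P = branch_transition_matrices(Q, tree.blen)
    down, logsc = _down_pass(tree, tip_part, P)

    up = np.zeros((tree.n_nodes, m))
    up[tree.root] = prior
    for node in tree.preorder():
        kids = tree.children[node]
        if not kids:
            continue
        msgs = [P[c] @ down[c] for c in kids]
        for ci, c in enumerate(kids):
            sib = up[node].copy()
            for cj, msg in enumerate(msgs):
                if cj != ci:
                    sib = sib * msg
            u = sib @ P[c]        # sum_i sib_i P[c][i, j]
            s = u.max()
            up[c] = u / s if s > 0 else u

    internals = np.arange(tree.n_tips, tree.n_nodes)
    probs = np.zeros((len(internals), m))
    for idx, node in enumerate(internals):
        joint = up[node] * down[node]
        probs[idx] = joint / joint.sum()
    labels = [tree.node_labels[i] if tree.node_labels else f"node{i}" for i in internals]
    return ASRResult(internals, labels, probs, list(range(m)))


def count_transitions(asr: ASRResult, tree: Phylogeny, states) -> dict:
    """Gains (0->1) and losses (1->0) along branches, comparing MAP states of
    parent and child (tips use their observed states)."""
    if isinstance(states, dict):
        states = [states[t] for t in tree.tip_labels]
    node_state = np.zeros(tree.n_nodes, dtype=int)
    node_state[: tree.n_tips] = [int(s) for s in states]
    maps = asr.map_states
    for idx, node in enumerate(asr.node_index):
        node_state[node] = maps[idx]
    gains = losses = 0
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p == -1:
            continue
        a, b = node_state[p], node_state[node]
        if a == 0 and b == 1:
            gains += 1
        elif a == 1 and b == 0:
            losses += 1
    ties = int(asr.tie_flags().sum())
    return {"gains": gains, "losses": losses, "ties_flagged": ties}


# ---------------------------------------------------------------------------
# Pagel's correlated-evolution test for two binary traits
# ---------------------------------------------------------------------------
#
# Combined state index for traits (x, y): 0 = (0,0), 1 = (0,1), 2 = (1,0),
# 3 = (1,1).  Transitions changing both traits at once have rate zero in both
# the independent (4-rate) and dependent (8-rate) models.

_PAIR_MOVES = [  # (from, to, x_change(0/1), direction) for single-trait moves
    (0, 2, "x", "01"), (2, 0, "x", "10"), (1, 3, "x", "01"), (3, 1, "x", "10"),
    (0, 1, "y", "01"), (1, 0, "y", "10"), (2, 3, "y", "01"), (3, 2, "y", "10"),
]


def _pair_q_independent(rates) -> np.ndarray:
    """4-state chain from two independent binary chains.

    ``rates`` = (qx01, qx10, qy01, qy10)."""
    qx01, qx10, qy01, qy10 = rates
    lookup = {("x", "01"): qx01, ("x", "10"): qx10,
              ("y", "01"): qy01, ("y", "10"): qy10}
    Q = np.zeros((4, 4))
    for frm, to, trait, d in _PAIR_MOVES:
        Q[frm, to] = lookup[(trait, d)]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _pair_q_dependent(rates) -> np.ndarray:
    """8 free rates: each single-trait transition rate may depend on the state
    of the other trait.  Order follows ``_PAIR_MOVES``."""
    Q = np.zeros((4, 4))
    for (frm, to, _, _), r in zip(_PAIR_MOVES, rates):
        Q[frm, to] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _fit_pair(tree, combined, build, n_rates, depth, prior, starts):
    def nll(logr):
        try:
            return -mk_loglik(tree, combined, build(np.exp(logr)), prior)
        except (ValueError, FloatingPointError):
            return 1e10

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(_RATE_LO), np.log(_RATE_HI))] * n_rates)
        if best is None or res.fun < best.fun:
            best = res
    return best


def pagel_dependence_test(tree: Phylogeny, x, y, root_prior=None) -> dict:
    """Test whether two binary traits evolve in a correlated fashion.

    The independent model couples two 2-state chains into a 4-state chain with
    4 free rates; the dependent model frees all 8 single-trait transition
    rates.  Dual transitions are forbidden in both.  Reports AIC for each
    model (the conventional statistic for this comparison), AICc, and a
    likelihood-ratio test with 4 degrees of freedom.
    """
    if isinstance(x, dict):
        x = [x[t] for t in tree.tip_labels]
    if isinstance(y, dict):
        y = [y[t] for t in tree.tip_labels]
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    for name, v in (("x", x), ("y", y)):
        if len(np.unique(v)) < 2:
            raise ValueError(f"cannot test dependence with invariant character {name}")
    combined = (2 * x + y).tolist()
    n = tree.n_tips
    depth = tree.depth()
    prior = np.full(4, 0.25) if root_prior is None else np.asarray(root_prior, float)

    base_starts = [np.full(4, np.log(s / depth)) for s in (0.1, 1.0, 10.0)]
    ind = _fit_pair(tree, combined, _pair_q_independent, 4, depth, prior, base_starts)
    ind_rates = np.exp(ind.x)
    # dependent starts: replicate the independent solution plus generic grids
    dep_from_ind = np.log(ind_rates[[0, 1, 0, 1, 2, 3, 2, 3]])
    dep_starts = [dep_from_ind] + [np.full(8, np.log(s / depth)) for s in (0.5, 5.0)]
    dep = _fit_pair(tree, combined, _pair_q_dependent, 8, depth, prior, dep_starts)

    lnL_ind, lnL_dep = -float(ind.fun), -float(dep.fun)
    if lnL_dep < lnL_ind - 1e-6:
        lnL_dep = lnL_ind  # optimizer slack on the nested model

    def mk(model, Q, lnL, k):
        aic = -2 * lnL + 2 * k
        aicc_val = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else np.nan
        return MkFit([0, 1, 2, 3], Q, model, lnL, k, n, aic, aicc_val, prior)

    fit_ind = mk("independent-pair", _pair_q_independent(np.exp(ind.x)), lnL_ind, 4)
    fit_dep = mk("dependent-pair", _pair_q_dependent(np.exp(dep.x)), lnL_dep, 8)
    test = lrt(lnL_ind, lnL_dep, df=4)
    return {
        "independent": fit_ind,
        "dependent": fit_dep,
        "aic_independent": fit_ind.aic,
        "aic_dependent": fit_dep.aic,
        "delta_aic": fit_ind.aic - fit_dep.aic,
        "dependent_rates": {f"{frm}->{to}": fit_dep.Q[frm, to]
                            for frm, to, _, _ in _PAIR_MOVES},
        "lrt": test,
    }
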