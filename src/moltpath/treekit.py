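"""Phylogeny container, Newick I/O, and phylogenetic covariance matrices.

The central object of every comparative analysis here is the phylogenetic
variance-covariance (VCV) matrix ``C``: under Brownian motion on the tree the
covariance between two tips equals the branch-length path shared from the root
to their most recent common ancestor.  All model-based analyses (Gaussian
trait models, PGLS, phylogenetic ANOVA, path analysis) consume either ``C``
itself or a parametric deformation of it (Pagel's lambda, Ornstein-Uhlenbeck,
early-burst).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "vcv_matrix",
    "transform_lambda",
    "transform_ou",
    "transform_eb",
    "lambda_max",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, stored as flat parent/child arrays.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``)
    in the order of ``tip_labels``.  The root has parent ``-1`` and branch
    length 0.  Polytomies are retained as-is; zero-length branches are legal.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 for root
    blen: np.ndarray            # (n_nodes,) float, 0 for root
    children: list              # list of lists of child indices
    tip_labels: list            # length n_tips
    node_labels: list = field(default_factory=list)  # labels for all nodes

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        self._validate()

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def _validate(self) -> None:
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.blen < 0):
            raise ValueError("negative branch lengths are not allowed")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        # acyclicity / connectivity: every node must reach the root
        for i in range(self.n_nodes):
            seen = set()
            j = i
            while j != -1:
                if j in seen:
                    raise ValueError("cycle detected in parent links")
                seen.add(j)
                j = int(self.parent[j])

    # -- traversals --------------------------------------------------------
    def postorder(self) -> list:
        """Node indices, children always before parents."""
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self) -> list:
        return self.postorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p != -1:
                d[node] = d[p] + self.blen[node]
        return d

    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.depths()[: self.n_tips].max())

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    def prune_to(self, keep: list) -> "Phylogeny":
        """Restriction of the tree to a subset of tips.

        Degree-two internal nodes created by pruning are suppressed (their
        two incident branches are merged), matching the usual behaviour of
        tree-pruning utilities.
        """
        keep = list(keep)
        missing = [k for k in keep if k not in self.tip_labels]
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        dtree = _to_dendropy(self)
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        return _from_dendropy(dtree)

    # -- dunder ------------------------------------------------------------
    def __repr__(self):
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth():.4g})"


@dataclass
class PhyloCovariance:
    """Tip-by-tip covariance structure implied by a model on the tree."""

    matrix: np.ndarray
    tip_labels: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.tip_labels)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match tip labels")

    def check_psd(self, rtol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh((self.matrix + self.matrix.T) / 2)
        return bool(w.min() >= -rtol * max(np.trace(self.matrix), 1.0))

    def reorder(self, labels: list) -> "PhyloCovariance":
        idx = [self.tip_labels.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))


# ---------------------------------------------------------------------------
# Newick I/O (dendropy does the parsing; we convert to flat arrays)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    tips = [leaf for leaf in dtree.leaf_node_iter()]
    tip_labels = [leaf.taxon.label if leaf.taxon else (leaf.label or "") for leaf in tips]
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    index = {}
    for i, leaf in enumerate(tips):
        index[id(leaf)] = i
    for j, nd in enumerate(internals):
        index[id(nd)] = len(tips) + j
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list = [[] for _ in range(n)]
    labels = [""] * n
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        else:
            labels[i] = f"node{i}"
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            blen[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
            children[parent[i]].append(i)
    return Phylogeny(parent, blen, children, tip_labels, labels)


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)
    nodes = {}
    for i in tree.preorder():
        nd = dtree.seed_node if tree.parent[i] == -1 else dendropy.Node()
        if tree.parent[i] != -1:
            nodes[tree.parent[i]].add_child(nd)
            nd.edge.length = float(tree.blen[i])
        if i < tree.n_tips:
            nd.taxon = ns.new_taxon(tree.tip_labels[i])
        nodes[i] = nd
    return dtree


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Raises :class:`NewickParseError` (with the offending position when the
    parser reports one) for malformed input, and ``ValueError`` for duplicate
    tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    dtree = _to_dendropy(tree)
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Covariance construction and model transforms
# ---------------------------------------------------------------------------

def _tipsets(tree: Phylogeny) -> list:
    """Descendant tip index sets, one per node."""
    sets = [set() for _ in range(tree.n_nodes)]
    for node in tree.postorder():
        if node < tree.n_tips:
            sets[node] = {node}
        else:
            for c in tree.children[node]:
                sets[node] |= sets[c]
    return sets


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion VCV: ``C[i, j]`` = depth of MRCA(i, j), ``C[i, i]`` =
    root-to-tip distance of tip i."""
    n = tree.n_tips
    depths = tree.depths()
    sets = _tipsets(tree)
    C = np.zeros((n, n))
    for node in tree.postorder():
        if node < n:
            continue
        kids = tree.children[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.fromiter(sets[kids[a]], int)
                ib = np.fromiter(sets[kids[b]], int)
                C[np.ix_(ia, ib)] = depths[node]
                C[np.ix_(ib, ia)] = depths[node]
    C[np.diag_indices(n)] = depths[:n]
    return PhyloCovariance(C, list(tree.tip_labels))


def is_ultrametric(tree: Phylogeny, rtol: float = 1e-6) -> bool:
    d = tree.depths()[: tree.n_tips]
    return bool(d.max() - d.min() < rtol * max(d.max(), 1e-300))


def lambda_max(C: np.ndarray) -> float:
    """Largest Pagel's lambda keeping the transformed matrix PSD.

    Bounded above by ``min_{i != j, Cij>0} sqrt(Cii*Cjj)/Cij``; for ultrametric
    trees this equals ``max_depth / max_offdiag``.  A final bisection refines
    against the actual eigenvalue criterion.
    """
    C = np.asarray(C)
    n = C.shape[0]
    off = C[~np.eye(n, dtype=bool)]
    pos = off[off > 0]
    if len(pos) == 0:
        return 1.0
    d = np.sqrt(np.outer(np.diag(C), np.diag(C)))
    mask = ~np.eye(n, dtype=bool) & (C > 0)
    hi = float(np.min(d[mask] / C[mask]))

    def psd(lam):
        M = lam * C
        np.fill_diagonal(M, np.diag(C))
        w = np.linalg.eigvalsh(M)
        return w.min() >= -1e-10 * np.trace(C)

    if psd(hi):
        return hi
    lo = 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if psd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def transform_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: off-diagonals scaled by ``lam``, diagonal unchanged."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    lmax = lambda_max(C.matrix)
    if lam > lmax + 1e-9:
        raise ValueError(f"lambda={lam} exceeds PSD bound {lmax:.6g}")
    M = lam * C.matrix
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(M, list(C.tip_labels))


def transform_ou(C: PhyloCovariance, alpha: float) -> PhyloCovariance:
    """Fixed-root Ornstein-Uhlenbeck covariance (sigma^2 factored out).

    ``V_ij = exp(-alpha * d_ij) * (1 - exp(-2 alpha T_ij)) / (2 alpha)`` where
    ``T_ij`` is the shared root-to-MRCA time and ``d_ij`` the tip-to-tip
    patristic distance.  As ``alpha -> 0`` this tends to the BM matrix
    ``T_ij``.  On ultrametric trees it reduces to the familiar stationary
    form.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    T = C.matrix
    diag = np.diag(T)
    d = diag[:, None] + diag[None, :] - 2 * T
    if alpha == 0:
        return PhyloCovariance(T.copy(), list(C.tip_labels))
    with np.errstate(over="ignore"):
        V = np.exp(-alpha * d) * -np.expm1(-2 * alpha * T) / (2 * alpha)
    return PhyloCovariance(V, list(C.tip_labels))


def transform_eb(tree: Phylogeny, r: float) -> PhyloCovariance:
    """Early-burst: each branch spanning ages t1 -> t2 is replaced by
    ``(exp(r t2) - exp(r t1)) / r`` (rates decay exponentially through time,
    so ``r <= 0``), then the standard VCV is taken."""
    if r > 0:
        raise ValueError("EB decay parameter r must be <= 0")
    if r == 0:
        return vcv_matrix(tree)
    depths = tree.depths()
    new_blen = tree.blen.copy()
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p == -1:
            continue
        t1, t2 = depths[p], depths[node]
        # (exp(r t2) - exp(r t1)) / r, written to avoid cancellation as r -> 0
        new_blen[node] = np.exp(r * t1) * np.expm1(r * (t2 - t1)) / r
    scaled = Phylogeny(tree.parent.copy(), new_blen, [list(c) for c in tree.children],
                       list(tree.tip_labels), list(tree.node_labels))
    return vcv_matrix(scaled)


def transform_tree(tree: Phylogeny, model: str, value: float) -> PhyloCovariance:
    """Dispatch on model name: ``lambda``, ``ou`` or ``eb``."""
    if model == "lambda":
        return transform_lambda(vcv_matrix(tree), value)
    if model == "ou":
        return transform_ou(vcv_matrix(tree), value)
    if model == "eb":
        return transform_eb(tree, value)
    raise ValueError(f"unknown transform model {model!r}")
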