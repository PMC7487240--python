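"""Phylogenetic path analysis by d-separation.

A candidate causal hypothesis is a DAG over the observed variables.  Its
testable content is the *basis set* of conditional independencies: one claim
per non-adjacent vertex pair, conditioning on the union of both vertices'
parents.  Each claim is tested with a phylogenetic regression (the
topologically later variable regressed on the earlier plus the conditioning
set; the claim's p-value is the two-sided p of the earlier variable's
coefficient).  Claim p-values combine into Fisher's
``C = -2 sum(ln p_i)`` which is chi-square with ``2k`` degrees of freedom
when the DAG is true; competing DAGs are ranked by
``CICc = C + 2 q n / (n - 1 - q)`` where ``q`` counts free parameters
(directed edges plus one variance per vertex by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pgls_regression import pgls_fit
from .treekit import Phylogeny

__all__ = [
    "CausalDAG",
    "IndependenceClaim",
    "PathModelResult",
    "basis_set",
    "test_claims",
    "fisher_c",
    "cicc",
    "evaluate_path_models",
    "read_dag_set",
    "default_dag_set",
]


@dataclass
class CausalDAG:
    name: str
    edges: list  # (parent, child) tuples

    def __post_init__(self):
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"graph {self.name!r} contains a cycle: {cycle}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def vertices(self, extra=()) -> list:
        v = set(self._graph.nodes) | set(extra)
        return sorted(v)

    def q(self, extra_vertices=()) -> int:
        """Free-parameter count: directed edges + one variance per vertex."""
        return len(self.edges) + len(self.vertices(extra_vertices))


@dataclass
class IndependenceClaim:
    x: str              # causally earlier variable
    y: str              # causally later variable (regression response)
    conditioning: tuple
    p: float | None = None


@dataclass
class PathModelResult:
    model: str
    k: int              # number of independence claims
    C: float
    p: float
    q: int
    n: int
    cicc: float
    rejected: bool
    rank: int | None = None
    claims: list = field(default_factory=list)


def basis_set(dag: CausalDAG, extra_vertices=()) -> list:
    """Conditional-independence basis set of a DAG.

    One claim per unordered non-adjacent pair; the causally later vertex (in
    a deterministic lexicographic topological order) is the response, the
    conditioning set is the union of both vertices' parents minus the pair.
    ``extra_vertices`` adds isolated variables that the DAG leaves
    unconnected (they are then non-adjacent to everything).
    """
    g = dag.graph.copy()
    for v in extra_vertices:
        g.add_node(v)
    topo = list(nx.lexicographical_topological_sort(g))
    pos = {v: i for i, v in enumerate(topo)}
    claims = []
    verts = sorted(g.nodes)
    for i, a in enumerate(verts):
        for b in verts[i + 1:]:
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            x, y = (a, b) if pos[a] < pos[b] else (b, a)
            Z = (set(g.predecessors(a)) | set(g.predecessors(b))) - {a, b}
            claims.append(IndependenceClaim(x, y, tuple(sorted(Z))))
    claims.sort(key=lambda c: tuple(sorted((c.x, c.y))))
    return claims


def test_claims(tree: Phylogeny, data: pd.DataFrame, claims: list,
                correlation: str = "BM") -> list:
    """Attach a PGLS p-value to every claim.

    Each claim tests ``y ~ x + Z`` and records the two-sided p of the ``x``
    coefficient.
    """
    out = []
    for claim in claims:
        cols = [claim.x, *claim.conditioning]
        fit = pgls_fit(tree, data[claim.y], data[cols], correlation=correlation,
                       response=claim.y, predictors=cols)
        p = float(fit.p_coef[1])  # coefficient of x (intercept is first)
        out.append(IndependenceClaim(claim.x, claim.y, claim.conditioning, p))
    return out


def fisher_c(pvalues) -> dict:
    """Combine independence-claim p-values: ``C = -2 sum ln p``, chi-square
    with ``2k`` df.  Zero p-values are clamped to 1e-300 (with a warning flag
    in the result)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    clamped = p <= 0
    p = np.where(clamped, 1e-300, p)
    C = float(-2.0 * np.sum(np.log(p)))
    df = 2 * len(p)
    return {"C": C, "df": df, "p": float(chi2.sf(C, df)),
            "clamped": int(clamped.sum())}


def cicc(C: float, q: int, n: int) -> float:
    """Small-sample information criterion for d-sep models."""
    if n <= q + 1:
        raise ValueError(f"CICc undefined: n={n} <= q+1={q + 1}")
    return C + 2.0 * q * n / (n - 1.0 - q)


def evaluate_path_models(tree: Phylogeny, data: pd.DataFrame, dags: list,
                         alpha: float = 0.05, correlation: str = "BM",
                         variables: list | None = None) -> list:
    """Test and rank candidate path models.

    Every DAG is evaluated over the shared variable set (``variables`` or the
    union of all DAG vertices); models whose C-statistic p-value falls below
    ``alpha`` are flagged rejected; the non-rejected subset is ranked
    ascending by CICc (rejected models get ranks after all surviving ones).
    """
    if not dags:
        raise ValueError("need at least one candidate DAG")
    if variables is None:
        variables = sorted(set().union(*(d.vertices() for d in dags)))
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")
    n = tree.n_tips
    results = []
    for dag in dags:
        extra = [v for v in variables if v not in dag.graph.nodes]
        claims = basis_set(dag, extra_vertices=extra)
        q = dag.q(extra)
        if claims:
            tested = test_claims(tree, data, claims, correlation=correlation)
            comb = fisher_c([c.p for c in tested])
            C, p = comb["C"], comb["p"]
        else:
            tested, C, p = [], 0.0, 1.0
        results.append(PathModelResult(dag.name, len(claims), C, p, q, n,
                                       cicc(C, q, n), rejected=p <= alpha,
                                       claims=tested))
    order = sorted(results, key=lambda r: (r.rejected, r.cicc))
    for rank, res in enumerate(order, start=1):
        res.rank = rank
    return results


def results_table(results: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"model": r.model, "k": r.k, "C": r.C, "p": r.p, "q": r.q,
         "n": r.n, "CICc": r.cicc, "rejected": r.rejected, "rank": r.rank}
        for r in sorted(results, key=lambda r: r.rank)
    ])


# ---------------------------------------------------------------------------
# Candidate model sets (plain-text edge-list format)
# ---------------------------------------------------------------------------

def read_dag_set(path) -> list:
    """Parse a plain-text DAG set: blocks starting ``id: <name>`` followed by
    ``parent -> child`` lines; ``#`` comments and blank lines ignored."""
    dags, name, edges = [], None, []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("id:"):
                if name is not None:
                    dags.append(CausalDAG(name, edges))
                name, edges = line.split(":", 1)[1].strip(), []
            elif "->" in line:
                a, b = (s.strip() for s in line.split("->", 1))
                edges.append((a, b))
            else:
                raise ValueError(f"unparseable line in DAG set: {raw!r}")
    if name is not None:
        dags.append(CausalDAG(name, edges))
    return dags


def default_dag_set() -> list:
    """The bundled 12-model candidate set over migration distance, day
    length, foraging stratum, prealternate molt and seasonal dichromatism."""
    from importlib.resources import files
    return read_dag_set(files("moltpath.data") / "candidate_dags.txt")
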