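"""Perturbation graphs and graph-consistent node free energies.

A relative free-energy campaign computes predicted ddGs for a subset of
ligand pairs; ligands are nodes and predicted pairs are edges.  Raw edge
predictions generally violate thermodynamic cycle closure (the signed sum of
ddGs around a loop must be zero).  A self-consistent set of per-ligand dGs —
defined up to one additive constant — is obtained here by weighted least
squares on the graph incidence matrix:

    minimize  sum_e w_e (dg_a - dg_b - ddg_e)^2

with w_e = 1/se_e^2 when every edge carries a standard error, unit weights
otherwise.  The gauge is fixed by mean-centering the node estimates, which
makes the result invariant under node relabeling.  Fitted edge ddGs
(dg_a - dg_b) close every cycle exactly.

Sign convention: an edge (a, b, ddg) predicts ddG_ab = dG_a - dG_b.
All downstream pairwise metrics are invariant to this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np

from .exceptions import GraphConnectivityError, RbfeError


@dataclass(frozen=True)
class Edge:
    """One predicted perturbation a -> b with ddg = dG_a - dG_b (kcal/mol)."""

    a: str
    b: str
    ddg: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise RbfeError(f"self-edge on node {self.a!r} is not allowed")
        if self.se is not None and not self.se > 0:
            raise RbfeError(f"edge ({self.a}, {self.b}): standard error must be > 0")


@dataclass
class PerturbationGraph:
    """Ligands as nodes, predicted ddG edges; optional experimental dGs.

    Duplicate (a, b) edges are kept as independent observations.  Extra
    nodes (present in ``exp_dg`` but not on any edge) are ignored.
    """

    edges: List[Edge]
    exp_dg: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [e if isinstance(e, Edge) else Edge(*e) for e in self.edges]
        if len(self.edges) < 1:
            raise RbfeError("perturbation graph needs at least one edge")

    @property
    def nodes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.a)
            seen.setdefault(e.b)
        return sorted(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, ddg=e.ddg, se=e.se)
        return g

    def require_connected(self) -> None:
        g = self.to_networkx()
        if not nx.is_connected(g):
            raise GraphConnectivityError(nx.connected_components(g))


@dataclass(frozen=True)
class NodeEstimate:
    """A ligand's inferred dG (mean-centered over the graph) in kcal/mol."""

    compound_id: str
    dg: float
    dg_se: Optional[float] = None


def _edge_weights(g: PerturbationGraph) -> np.ndarray:
    ses = [e.se for e in g.edges]
    if all(s is not None for s in ses):
        return 1.0 / np.asarray(ses, dtype=float) ** 2
    if any(s is not None for s in ses):
        warnings.warn(
            "some edges lack standard errors; falling back to unit weights",
            stacklevel=3,
        )
    return np.ones(len(ses))


def infer_node_dgs(g: PerturbationGraph) -> List[NodeEstimate]:
    """Infer mean-centered per-ligand dGs by weighted least squares.

    Returns one :class:`NodeEstimate` per node, sorted by compound id.  Node
    standard errors come from the pseudo-inverse of the weighted normal
    matrix: directly when edge SEs define the weights, scaled by the
    residual variance (with E - (N - 1) degrees of freedom) under unit
    weights; a cycle-free unit-weight graph gets SEs of 0.
    """
    g.require_connected()
    nodes = g.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n_nodes, n_edges = len(nodes), len(g.edges)

    a_mat = np.zeros((n_edges, n_nodes))
    d = np.empty(n_edges)
    for row, e in enumerate(g.edges):
        a_mat[row, index[e.a]] = 1.0
        a_mat[row, index[e.b]] = -1.0
        d[row] = e.ddg

    w = _edge_weights(g)
    normal = a_mat.T @ (a_mat * w[:, None])
    cov = np.linalg.pinv(normal)
    # pinv solution is orthogonal to the constant null vector -> mean-centered
    dgs = cov @ (a_mat.T @ (w * d))

    weighted = any(e.se is not None for e in g.edges) and len(
        [e for e in g.edges if e.se is not None]
    ) == len(g.edges)
    if weighted:
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        dof = n_edges - (n_nodes - 1)
        if dof > 0:
            rss = float(w @ (a_mat @ dgs - d) ** 2)
            sigma2 = rss / dof
        else:
            sigma2 = 0.0
        ses = np.sqrt(np.clip(sigma2 * np.diag(cov), 0.0, None))

    return [NodeEstimate(n, float(dgs[i]), float(ses[i])) for n, i in index.items()]


def consistent_edge_ddgs(
    nodes: Sequence[NodeEstimate], g: PerturbationGraph
) -> List[float]:
    """Fitted ddG for every edge (a, b): dg_a - dg_b, in edge order.

    Being differences of node potentials, the fitted ddGs sum to zero around
    every cycle to machine precision.
    """
    dg = {n.compound_id: n.dg for n in nodes}
    graph_nodes = {e.a for e in g.edges} | {e.b for e in g.edges}
    missing = sorted(graph_nodes - dg.keys())
    if missing:
        raise RbfeError(f"node estimates missing for: {missing}")
    return [dg[e.a] - dg[e.b] for e in g.edges]


def align_offset(
    pred: Sequence[float], exp: Sequence[float]
) -> np.ndarray:
    """Shift predicted dGs so their mean matches the experimental mean.

    Purely cosmetic for scatter plots: correlations, rank statistics and all
    pairwise differences are unchanged.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or pred.size < 1:
        raise RbfeError(
            f"pred and exp must be equal-length 1-D sequences, "
            f"got {pred.shape} vs {exp.shape}"
        )
    return pred + (exp.mean() - pred.mean())
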