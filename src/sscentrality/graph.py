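"""Directed pathway graphs and their adjacency algebra.

A pathway is modelled as a simple directed graph ``G = (V, E)`` whose nodes
are gene-encoded elements and whose edges are directed interactions.  Every
matrix or vector derived from a :class:`PathwayGraph` indexes nodes in the
graph's declared node order, which is stable under transposition and
undirected projection.

Self-loops are dropped at construction time and duplicate edges collapse to
a single 0/1 adjacency entry: the centrality models operate on a strictly
binary adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse.linalg

__all__ = [
    "PathwayGraph",
    "AdjacencyBundle",
    "GraphFormatError",
    "from_edge_list",
    "read_edge_list",
    "transpose",
    "underlying_undirected",
    "degrees",
    "spectral_radius",
]

logger = logging.getLogger(__name__)

# dense eigendecomposition below this size, Arnoldi iteration above
_DENSE_EIG_LIMIT = 200


class GraphFormatError(ValueError):
    """Malformed edge-list or graph input."""


@dataclass(frozen=True)
class PathwayGraph:
    """A simple directed graph with a stable node order.

    Parameters
    ----------
    pathway_id : str
        Label of the pathway the graph represents.
    nodes : tuple of str
        Unique node identifiers; the canonical index order for all derived
        vectors and matrices.
    edges : tuple of (str, str)
        Directed edges as ordered pairs of node identifiers.  No duplicates,
        no self-loops.
    """

    pathway_id: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {v: i for i, v in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise GraphFormatError(
                f"{self.pathway_id}: duplicate node identifiers"
            )
        for u, v in self.edges:
            if u not in index or v not in index:
                raise GraphFormatError(
                    f"{self.pathway_id}: edge ({u}, {v}) references an "
                    "undeclared node"
                )
            if u == v:
                raise GraphFormatError(
                    f"{self.pathway_id}: self-loop on {u} not permitted"
                )
        if len(set(self.edges)) != len(self.edges):
            raise GraphFormatError(f"{self.pathway_id}: duplicate edges")
        object.__setattr__(self, "_index", index)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, node: str) -> int:
        return self._index[node]

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix A with A[i, j] = 1 iff (v_i, v_j) in E."""
        n = self.n_nodes
        A = np.zeros((n, n), dtype=float)
        for u, v in self.edges:
            A[self._index[u], self._index[v]] = 1.0
        return A

    def bundle(self) -> "AdjacencyBundle":
        return AdjacencyBundle.from_graph(self)


@dataclass(frozen=True)
class AdjacencyBundle:
    """Adjacency matrix together with clamped degree matrices.

    ``d_out`` and ``d_in`` hold the diagonals of the out- and in-degree
    matrices with every entry clamped to at least 1, matching the
    ``max(deg(v), 1)`` convention of the spectral centrality models.  The
    clamp applies only here — degree centrality itself reports unclamped
    degrees.
    """

    A: np.ndarray
    d_out: np.ndarray
    d_in: np.ndarray

    @classmethod
    def from_graph(cls, g: PathwayGraph) -> "AdjacencyBundle":
        A = g.adjacency()
        d_out = np.maximum(A.sum(axis=1), 1.0)
        d_in = np.maximum(A.sum(axis=0), 1.0)
        return cls(A=A, d_out=d_out, d_in=d_in)

    def transposed(self) -> "AdjacencyBundle":
        return AdjacencyBundle(A=self.A.T.copy(), d_out=self.d_in, d_in=self.d_out)


def _validate_row(row: Sequence, i: int) -> tuple[str, str]:
    if len(row) < 2:
        raise GraphFormatError(f"row {i}: expected (source, target), got {row!r}")
    u, v = str(row[0]), str(row[1])
    if not u or not v:
        raise GraphFormatError(f"row {i}: empty node identifier in {row!r}")
    return u, v


def from_edge_list(
    rows: Iterable[Sequence],
    pathway_id: str = "pathway",
    nodes: Sequence[str] | None = None,
) -> PathwayGraph:
    """Build a :class:`PathwayGraph` from (source, target) pairs.

    Duplicate edges are collapsed, self-loops are dropped (logged with a
    count), and nodes are ordered by first appearance in the edge list;
    isolated nodes supplied via ``nodes`` are appended in lexicographic
    order.
    """
    order: list[str] = []
    seen: set[str] = set()
    edge_set: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    n_loops = 0
    n_rows = 0
    for i, row in enumerate(rows):
        n_rows += 1
        u, v = _validate_row(row, i)
        for w in (u, v):
            if w not in seen:
                seen.add(w)
                order.append(w)
        if u == v:
            n_loops += 1
            continue
        if (u, v) not in edge_set:
            edge_set.add((u, v))
            edges.append((u, v))
    if nodes is not None:
        for w in sorted(str(x) for x in nodes):
            if w not in seen:
                seen.add(w)
                order.append(w)
    if n_rows == 0 and not order:
        raise GraphFormatError(
            f"{pathway_id}: empty edge list and no explicit node list"
        )
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", pathway_id, n_loops)
    return PathwayGraph(pathway_id=pathway_id, nodes=tuple(order), edges=tuple(edges))


def read_edge_list(path, pathway_id: str | None = None) -> PathwayGraph:
    """Read a 2/3-column tab-separated edge list (``#`` comments ignored)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{i + 1}: expected 2 or 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts[:2])
    if pathway_id is None:
        import os

        pathway_id = os.path.splitext(os.path.basename(str(path)))[0]
    return from_edge_list(rows, pathway_id=pathway_id)


def transpose(g: PathwayGraph) -> PathwayGraph:
    """Reverse all edge directions; node set and order are unchanged."""
    return PathwayGraph(
        pathway_id=g.pathway_id,
        nodes=g.nodes,
        edges=tuple((v, u) for u, v in g.edges),
    )


def underlying_undirected(g: PathwayGraph) -> PathwayGraph:
    """Symmetrize the graph: each arc becomes a reciprocal pair.

    The undirected projection is represented as a symmetric directed graph
    so every centrality operation has a single code path.  The result is its
    own transpose and the projection is idempotent.
    """
    sym: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for u, v in g.edges:
        for e in ((u, v), (v, u)):
            if e not in sym:
                sym.add(e)
                edges.append(e)
    return PathwayGraph(pathway_id=g.pathway_id, nodes=g.nodes, edges=tuple(edges))


def degrees(g: PathwayGraph) -> tuple[np.ndarray, np.ndarray]:
    """Unclamped (out-degree, in-degree) vectors in node order."""
    A = g.adjacency()
    return A.sum(axis=1), A.sum(axis=0)


def spectral_radius(g: PathwayGraph, tol: float = 1e-9) -> float:
    """Largest eigenvalue modulus of the adjacency matrix.

    For a non-negative adjacency this equals the largest positive eigenvalue
    (Perron–Frobenius).  Dense eigendecomposition up to 200 nodes, sparse
    Arnoldi iteration above.
    """
    if g.n_nodes == 0:
        raise GraphFormatError(f"{g.pathway_id}: empty graph")
    A = g.adjacency()
    if g.n_nodes <= _DENSE_EIG_LIMIT:
        return float(np.max(np.abs(np.linalg.eigvals(A))))
    try:
        # shift by I: for non-negative A, rho(A + I) = rho(A) + 1 and the
        # dominant eigenvalue becomes real positive, which keeps Arnoldi
        # stable when A itself has several eigenvalues tied in modulus
        n = A.shape[0]
        shifted = scipy.sparse.csr_matrix(A) + scipy.sparse.identity(n)
        vals = scipy.sparse.linalg.eigs(
            shifted, k=1, which="LM", ncv=min(n, 50),
            v0=np.ones(n),  # deterministic start vector
            return_eigenvectors=False, tol=tol, maxiter=5_000,
        )
        return float(np.abs(vals[0])) - 1.0
    except scipy.sparse.linalg.ArpackNoConvergence as exc:
        # near-degenerate spectra (tiny gap ratios) defeat Arnoldi; fall
        # back to the dense solver while the matrix is still tractable
        if g.n_nodes <= 3000:
            return float(np.max(np.abs(np.linalg.eigvals(A))))
        raise ArithmeticError(
            f"{g.pathway_id}: eigenvalue iteration did not converge"
        ) from exc
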