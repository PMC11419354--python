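"""Directed acyclic graphs over named variables, and bow-free path models.

A linear structural equation model (SEM) attaches a coefficient ``B[j, k]``
to every directed edge ``k -> j`` of a DAG, so that each variable is a linear
combination of its graph parents plus an error term.  A bow-free acyclic path
(BAP) model extends the DAG with *bidirected* edges: unordered variable pairs
whose error terms are allowed to covary, under the bow-freeness constraint
that no pair carries both a directed and a bidirected edge.

This module provides the graph containers used everywhere else in the
package: deterministic topological ordering, parent sets, missing-edge
enumeration, bow-freeness validation, and GraphML / TSV edge-list I/O.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import networkx as nx


class GraphStructureError(ValueError):
    """Raised when an input graph violates the DAG invariants."""


class BowViolationError(ValueError):
    """Raised when a bidirected pair coincides with a directed edge."""


def _normalize_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class DirectedAcyclicGraph:
    """A weighted DAG with ordered, named nodes.

    Parameters
    ----------
    nodes
        Unique string labels.  Input order is preserved and used as the
        tie-breaking rule for the topological order, so runs are reproducible.
    edges
        ``(source, target)`` or ``(source, target, weight)`` tuples.  Weight
        defaults to 1.0.  Self-loops, duplicate edges, undeclared endpoints
        and directed cycles are rejected.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[Sequence] = (),
    ) -> None:
        self._nodes: Tuple[str, ...] = tuple(str(v) for v in nodes)
        if len(set(self._nodes)) != len(self._nodes):
            dupes = sorted({v for v in self._nodes if self._nodes.count(v) > 1})
            raise GraphStructureError(f"duplicate node labels: {dupes}")
        self._index: Dict[str, int] = {v: i for i, v in enumerate(self._nodes)}

        self._edges: List[Tuple[str, str, float]] = []
        self._parents: Dict[str, List[str]] = {v: [] for v in self._nodes}
        self._children: Dict[str, List[str]] = {v: [] for v in self._nodes}
        self._weight: Dict[Tuple[str, str], float] = {}
        for e in edges:
            if len(e) == 2:
                u, v, w = e[0], e[1], 1.0
            elif len(e) == 3:
                u, v, w = e
            else:
                raise GraphStructureError(f"edge must be (u, v[, weight]): {e!r}")
            u, v = str(u), str(v)
            for endpoint in (u, v):
                if endpoint not in self._index:
                    raise GraphStructureError(
                        f"edge ({u}, {v}) references undeclared node {endpoint!r}"
                    )
            if u == v:
                raise GraphStructureError(f"self-loop on node {u!r}")
            if (u, v) in self._weight:
                raise GraphStructureError(f"duplicate directed edge ({u}, {v})")
            self._weight[(u, v)] = float(w)
            self._edges.append((u, v, float(w)))
            self._parents[v].append(u)
            self._children[u].append(v)

        self._order: Tuple[str, ...] = self._kahn_order()

    # -- construction helpers ------------------------------------------------

    def _kahn_order(self) -> Tuple[str, ...]:
        """Kahn's algorithm with a FIFO queue seeded in input node order."""
        indeg = {v: len(self._parents[v]) for v in self._nodes}
        queue = deque(v for v in self._nodes if indeg[v] == 0)
        order: List[str] = []
        while queue:
            u = queue.popleft()
            order.append(u)
            for w in self._children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) != len(self._nodes):
            cycle = self._find_cycle({v for v in self._nodes if v not in set(order)})
            raise GraphStructureError(f"graph contains a directed cycle: {cycle}")
        return tuple(order)

    def _find_cycle(self, remaining: set) -> List[str]:
        start = next(v for v in self._nodes if v in remaining)
        seen: List[str] = []
        v = start
        while v not in seen:
            seen.append(v)
            v = next(u for u in self._parents[v] if u in remaining)
        i = seen.index(v)
        return seen[i:] + [v]

    # -- basic accessors -----------------------------------------------------

    @property
    def nodes(self) -> Tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> List[Tuple[str, str, float]]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._weight

    def weight(self, u: str, v: str) -> float:
        return self._weight[(u, v)]

    def parents(self, node: str) -> FrozenSet[str]:
        """Sources of directed edges into ``node``."""
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")
        return frozenset(self._parents[node])

    def children(self, node: str) -> FrozenSet[str]:
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")
        return frozenset(self._children[node])

    def source_nodes(self) -> List[str]:
        """Exogenous variables: nodes with no incoming edge."""
        return [v for v in self._nodes if not self._parents[v]]

    # -- spec operations -----------------------------------------------------

    def topological_order(self) -> List[str]:
        """Causal order: every directed edge points forward in the result."""
        return list(self._order)

    def missing_edges(self) -> List[Tuple[str, str]]:
        """All unordered node pairs with no directed edge in either direction.

        The count equals ``p(p-1)/2 - n_edges`` and is the number of degrees
        of freedom of the DAG as a SEM.
        """
        out: List[Tuple[str, str]] = []
        for i, u in enumerate(self._nodes):
            for v in self._nodes[i + 1 :]:
                if (u, v) not in self._weight and (v, u) not in self._weight:
                    out.append((u, v))
        return out

    def coefficient_matrix(self):
        """Dense coefficient matrix ``B`` with ``B[j, k]`` the weight of edge
        ``k -> j`` (rows index targets), in node order."""
        import numpy as np

        p = self.n_nodes
        B = np.zeros((p, p))
        for u, v, w in self._edges:
            B[self._index[v], self._index[u]] = w
        return B

    # -- conversions and I/O -------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for u, v, w in self._edges:
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedAcyclicGraph":
        if not g.is_directed():
            raise GraphStructureError("expected a directed graph")
        edges = [
            (u, v, float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)
        ]
        return cls(list(g.nodes()), edges)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "DirectedAcyclicGraph":
        return cls.from_networkx(nx.read_graphml(path))

    def write_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in self._edges:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")

    @classmethod
    def read_edgelist_tsv(cls, path) -> "DirectedAcyclicGraph":
        """Read a ``source<TAB>target[<TAB>weight]`` edge list (header required).

        Nodes are declared implicitly, in first-appearance order.
        """
        edges: List[Tuple[str, str, float]] = []
        nodes: List[str] = []
        seen = set()
        with open(path) as fh:
            header = fh.readline().strip().lower().split("\t")
            if header[:2] != ["source", "target"]:
                raise GraphStructureError(
                    f"edge list must start with a 'source\\ttarget' header, got {header}"
                )
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                u, v = parts[0], parts[1]
                w = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
                for x in (u, v):
                    if x not in seen:
                        seen.add(x)
                        nodes.append(x)
                edges.append((u, v, w))
        return cls(nodes, edges)

    # -- misc ----------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedAcyclicGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"DirectedAcyclicGraph(p={self.n_nodes}, edges={self.n_edges})"
        )


@dataclass(frozen=True)
class BAPModel:
    """A DAG plus a set of bidirected (bow-free) pairs.

    The bidirected pairs encode the off-diagonal support of the error
    covariance matrix Psi: a pair ``{j, k}`` means the errors of ``j`` and
    ``k`` are allowed to covary (an unobserved confounder acts on both).
    """

    dag: DirectedAcyclicGraph
    bidirected: FrozenSet[Tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(
            self,
            "bidirected",
            frozenset(_normalize_pair(*p) for p in self.bidirected),
        )


def validate_bap(
    dag: DirectedAcyclicGraph,
    bidirected: Iterable[Tuple[str, str]],
) -> BAPModel:
    """Validate bow-freeness and build a :class:`BAPModel`.

    A pair may not coincide with a directed edge in either orientation, must
    reference declared nodes, and must join two distinct nodes.
    """
    pairs = [_normalize_pair(str(a), str(b)) for a, b in bidirected]
    bad_nodes = sorted(
        {x for p in pairs for x in p if x not in dag.nodes}
    )
    if bad_nodes:
        raise GraphStructureError(
            f"bidirected pairs reference unknown nodes: {bad_nodes}"
        )
    loops = [p for p in pairs if p[0] == p[1]]
    if loops:
        raise GraphStructureError(f"bidirected self-pairs not allowed: {loops}")
    bows = sorted(
        {p for p in pairs if dag.has_edge(p[0], p[1]) or dag.has_edge(p[1], p[0])}
    )
    if bows:
        raise BowViolationError(
            f"bow violation: pairs share a directed edge: {bows}"
        )
    return BAPModel(dag=dag, bidirected=frozenset(pairs))


def align_columns(dag: DirectedAcyclicGraph, columns: Sequence[str]) -> List[str]:
    """Check that every graph node has a matching data column (case-sensitive).

    Returns the node list (the column order to use).  Raises with the full
    list of unmatched names on mismatch.
    """
    missing = [v for v in dag.nodes if v not in set(columns)]
    if missing:
        raise KeyError(
            "data matrix is missing columns for graph nodes: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return list(dag.nodes)
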