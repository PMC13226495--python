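"""Hydrogen-suppressed molecular graphs and their edge partitions.

A molecule is modelled as a simple, connected, undirected graph whose
vertices are the heavy (non-hydrogen) atoms and whose edges are bonds.
Bond order is deliberately ignored: every bonded pair of heavy atoms
contributes exactly one edge, which is the convention under which the
bundled edge-partition tables were tallied.

Two per-vertex labellings drive everything downstream:

* the *degree* ``d(v)``, the number of neighbours of ``v``;
* the *neighborhood degree* ``nd(v)``, the sum of the degrees of the
  neighbours of ``v``.

An :class:`EdgePartition` tallies the edges of a graph by the sorted pair
``(l, m)`` of endpoint labels under one of those two flavors.  It is the
only input the index computations need.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

#: Label flavor for plain vertex degrees.
DEGREE = "degree"
#: Label flavor for neighborhood degrees (sum of neighbour degrees).
NEIGHBORHOOD = "neighborhood"
FLAVORS = (DEGREE, NEIGHBORHOOD)

#: Valence bound for heavy atoms in organic drug skeletons.
MAX_VALENCE = 4


class GraphError(ValueError):
    """Invalid molecular graph or malformed edge-list input."""


def _check_flavor(flavor: str) -> str:
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
    return flavor


class MolecularGraph:
    """Simple connected graph of heavy atoms with a valence cap.

    Parameters
    ----------
    edges :
        Iterable of vertex-label pairs, one per bond.  Labels are opaque
        strings; no element typing is needed for any computation here.
    max_degree :
        Valence bound enforced on every vertex (default 4).

    Raises
    ------
    GraphError
        On self-loops, duplicate edges, disconnected input, isolated
        vertices or a vertex exceeding ``max_degree``.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], *, max_degree: int = MAX_VALENCE):
        g = nx.Graph()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphError(f"self-loop at vertex {u!r}")
            if g.has_edge(u, v):
                raise GraphError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v)
        if g.number_of_edges() == 0:
            raise GraphError("graph has no edges")
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise GraphError(f"graph is disconnected; components: {comps}")
        for v, d in g.degree():
            if d > max_degree:
                raise GraphError(f"vertex {v!r} has degree {d} > valence bound {max_degree}")
        self._g = g
        self.max_degree = max_degree

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(self._g.nodes())

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._g.edges())

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, v: str) -> tuple[str, ...]:
        return tuple(self._g.neighbors(v))

    def relabel(self, mapping: Mapping[str, str]) -> "MolecularGraph":
        """Return a copy with vertices renamed through ``mapping``."""
        return MolecularGraph(
            ((mapping[u], mapping[v]) for u, v in self.edges),
            max_degree=self.max_degree,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of sorted endpoint-label pairs ``(l, m)`` with counts.

    ``flavor`` records whether the labels are degrees or neighborhood
    degrees; the sum of all counts equals the edge count of the source
    graph.
    """

    flavor: str
    counts: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_flavor(self.flavor)
        norm: dict[tuple[int, int], int] = {}
        for (l, m), c in self.counts.items():
            l, m = int(l), int(m)
            if l > m:
                l, m = m, l
            if l < 1:
                raise ValueError(f"partition labels must be >= 1, got ({l},{m})")
            if self.flavor == DEGREE and m > MAX_VALENCE:
                raise ValueError(f"degree label {m} exceeds valence bound {MAX_VALENCE}")
            if int(c) <= 0:
                raise ValueError(f"cell ({l},{m}) has nonpositive count {c}")
            norm[(l, m)] = norm.get((l, m), 0) + int(c)
        object.__setattr__(self, "counts", norm)

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())

    def cells(self) -> Iterator[tuple[int, int, int]]:
        """Yield ``(l, m, count)`` in sorted cell order."""
        for (l, m) in sorted(self.counts):
            yield l, m, self.counts[(l, m)]

    def __len__(self) -> int:
        return len(self.counts)


def vertex_degrees(graph: MolecularGraph) -> dict[str, int]:
    """Map every vertex to its number of neighbours."""
    return {v: d for v, d in graph._g.degree()}


def neighborhood_degrees(graph: MolecularGraph) -> dict[str, int]:
    """Map every vertex ``v`` to ``nd(v)``, the sum of its neighbours' degrees."""
    deg = vertex_degrees(graph)
    return {v: sum(deg[u] for u in graph.neighbors(v)) for v in graph.vertices}


def edge_partition(graph: MolecularGraph, flavor: str = DEGREE) -> EdgePartition:
    """Tally the edges of ``graph`` by sorted endpoint labels.

    With ``flavor="degree"`` the labels are vertex degrees; with
    ``flavor="neighborhood"`` they are neighborhood degrees.
    """
    _check_flavor(flavor)
    label = vertex_degrees(graph) if flavor == DEGREE else neighborhood_degrees(graph)
    tally = Counter(tuple(sorted((label[u], label[v]))) for u, v in graph.edges)
    return EdgePartition(flavor, dict(tally))


def read_graph(text: str, *, max_degree: int = MAX_VALENCE) -> MolecularGraph:
    """Parse an edge-list document into a :class:`MolecularGraph`.

    Format: UTF-8 text, one bond per line as two whitespace-separated
    vertex labels; ``#`` starts a comment; blank lines ignored.
    """
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphError(f"line {lineno}: expected two vertex labels, got {raw!r}")
        u, v = parts
        if u == v:
            raise GraphError(f"line {lineno}: self-loop at vertex {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise GraphError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise GraphError("edge-list document contains no edges")
    return MolecularGraph(edges, max_degree=max_degree)


def write_graph(graph: MolecularGraph) -> str:
    """Serialize a graph back to the edge-list format."""
    return "".join(f"{u} {v}\n" for u, v in graph.edges)
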