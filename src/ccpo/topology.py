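"""Chain topologies of polyhedral coiled-coil cages.

A single-chain polyhedral cage traverses every edge of its target graph
exactly twice (once per peptide of the coiled-coil dimer occupying that
edge), so the chain corresponds to a closed *double trace* of the graph.
Physically realizable cage topologies additionally satisfy

* **properness** -- the walk never immediately retraces the edge it just
  traversed (a zero-length hairpin is not a coiled coil), and
* **strongness** -- at every vertex the walk's passages form a single
  cyclic corner: the multigraph whose nodes are the incident edges and
  whose links are the (in-edge, out-edge) transitions of the walk is
  connected.  This keeps each vertex a single junction instead of two or
  more independent crossings.

Double traces are grouped into topology classes under cyclic rotation,
walk reversal and graph automorphism.  The tetrahedron admits exactly
three such classes.  An edge whose two traversals run in the same
direction must be occupied by a parallel CC dimer, otherwise by an
antiparallel one; on the tetrahedron every class carries at least two
antiparallel edges.

Class labels ("T1", "T2", ...) and circular-permutation labels
("T1.1" ... "T1.12") follow this package's canonical ordering
(lexicographically minimal walk encoding).  They are stable across runs
but are a package convention: numbering used elsewhere (for instance
"circular permutation 1.10" in the experimental literature) need not
coincide with it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx

from ccpo.errors import SchemaError

Vertex = object
Step = tuple  # directed edge traversal (u, v)

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"

_NAMED_GRAPHS = {
    "tetrahedron": (
        (0, 1, 2, 3),
        ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),
    ),
}


@dataclass(frozen=True, init=False)
class PolyhedronGraph:
    """Simple connected graph whose edges are realized by CC dimers."""

    vertices: tuple
    edges: tuple  # tuple of 2-tuples, each sorted by vertex order

    def __init__(self, vertices: Iterable, edges: Iterable):
        verts = tuple(vertices)
        if len(set(verts)) != len(verts):
            raise SchemaError("duplicate vertex labels")
        if not verts:
            raise SchemaError("graph has no vertices")
        order = {v: i for i, v in enumerate(verts)}
        norm = []
        for e in edges:
            u, v = tuple(e)
            if u == v:
                raise SchemaError(f"self-loop on vertex {u!r} not allowed")
            if u not in order or v not in order:
                raise SchemaError(f"edge {e!r} references unknown vertex")
            key = (u, v) if order[u] < order[v] else (v, u)
            norm.append(key)
        if len(set(norm)) != len(norm):
            raise SchemaError("multi-edges not allowed")
        if not norm:
            raise SchemaError("graph has no edges")
        g = nx.Graph()
        g.add_nodes_from(verts)
        g.add_edges_from(norm)
        if not nx.is_connected(g):
            raise SchemaError("graph must be connected")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "edges", tuple(sorted(norm, key=lambda e: (order[e[0]], order[e[1]]))))

    @classmethod
    def named(cls, name: str) -> "PolyhedronGraph":
        try:
            verts, edges = _NAMED_GRAPHS[name]
        except KeyError:
            raise SchemaError(
                f"unknown named graph {name!r}; available: {sorted(_NAMED_GRAPHS)}"
            ) from None
        return cls(verts, edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_key(self, u, v) -> tuple:
        order = {w: i for i, w in enumerate(self.vertices)}
        return (u, v) if order[u] < order[v] else (v, u)

    def edge_index(self, u, v) -> int:
        return self.edges.index(self.edge_key(u, v))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def automorphisms(self) -> list[dict]:
        g = self.to_networkx()
        gm = nx.algorithms.isomorphism.GraphMatcher(g, g)
        return list(gm.isomorphisms_iter())


@dataclass(frozen=True)
class DoubleTrace:
    """Closed walk traversing every edge of ``graph`` exactly twice."""

    graph: PolyhedronGraph
    walk: tuple  # cyclic tuple of directed steps (u, v)

    def __post_init__(self):
        L = len(self.walk)
        if L != 2 * self.graph.n_edges:
            raise SchemaError("walk length must be twice the edge count")
        counts: dict = {}
        for i, (u, v) in enumerate(self.walk):
            nxt = self.walk[(i + 1) % L]
            if v != nxt[0]:
                raise SchemaError("walk is not a closed walk")
            key = self.graph.edge_key(u, v)
            counts[key] = counts.get(key, 0) + 1
        if set(counts) != set(self.graph.edges) or any(c != 2 for c in counts.values()):
            raise SchemaError("walk must traverse every edge exactly twice")

    @property
    def length(self) -> int:
        return len(self.walk)

    def vertex_sequence(self) -> tuple:
        return tuple(u for u, _ in self.walk)

    def is_proper(self) -> bool:
        L = len(self.walk)
        for i in range(L):
            u, v = self.walk[i]
            u2, v2 = self.walk[(i + 1) % L]
            if self.graph.edge_key(u, v) == self.graph.edge_key(u2, v2):
                return False
        return True

    def is_strong(self) -> bool:
        return _is_strong(self.graph, self.walk)

    def reversed(self) -> "DoubleTrace":
        rev = tuple((v, u) for (u, v) in reversed(self.walk))
        return DoubleTrace(self.graph, rev)

    def rotated(self, k: int) -> "DoubleTrace":
        k %= len(self.walk)
        return DoubleTrace(self.graph, self.walk[k:] + self.walk[:k])


def _is_strong(graph: PolyhedronGraph, walk: Sequence[Step]) -> bool:
    """Single-corner condition: at each vertex the transition multigraph
    over incident edges (one link per passage) is connected."""
    L = len(walk)
    transitions: dict = {v: [] for v in graph.vertices}
    for i in range(L):
        u, v = walk[i]
        nxt = walk[(i + 1) % L]
        e_in = graph.edge_key(u, v)
        e_out = graph.edge_key(*nxt)
        transitions[v].append((e_in, e_out))
    for v, trans in transitions.items():
        incident = [e for e in graph.edges if v in e]
        if len(trans) != len(incident):  # every passage visits once per degree
            return False
        parent = {e: e for e in incident}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in trans:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        roots = {find(e) for e in incident}
        if len(roots) != 1:
            return False
    return True


def enumerate_double_traces(
    graph: PolyhedronGraph,
    require_proper: bool = True,
    require_strong: bool = True,
) -> list[DoubleTrace]:
    """Exhaustively enumerate double traces of ``graph``.

    Backtracking over directed-edge extensions.  Walks are anchored at the
    lexicographically first edge of the graph (both traversal directions
    are used as starting arcs), so every cyclic walk is reported in at
    least one rotation; grouping by :func:`group_topologies` removes the
    remaining redundancy.
    """
    if not isinstance(graph, PolyhedronGraph):
        raise SchemaError("enumerate_double_traces requires a PolyhedronGraph")
    E = graph.n_edges
    L = 2 * E
    adj: dict = {v: [] for v in graph.vertices}
    for (u, v) in graph.edges:
        adj[u].append(v)
        adj[v].append(u)

    anchor = graph.edges[0]
    results: list[DoubleTrace] = []
    seen: set = set()

    def extend(walk: list, counts: dict):
        if len(walk) == L:
            u, v = walk[-1]
            if v != walk[0][0]:
                return
            if require_proper and graph.edge_key(u, v) == graph.edge_key(*walk[0]):
                return
            wt = tuple(walk)
            if wt in seen:
                return
            if require_strong and not _is_strong(graph, wt):
                return
            seen.add(wt)
            results.append(DoubleTrace(graph, wt))
            return
        here = walk[-1][1]
        prev_edge = graph.edge_key(*walk[-1])
        for nb in adj[here]:
            e = graph.edge_key(here, nb)
            if counts.get(e, 0) >= 2:
                continue
            if require_proper and e == prev_edge:
                continue
            counts[e] = counts.get(e, 0) + 1
            walk.append((here, nb))
            extend(walk, counts)
            walk.pop()
            counts[e] -= 1

    for start in (anchor, (anchor[1], anchor[0])):
        extend([start], {anchor: 1})
    return results


@dataclass(frozen=True)
class TopologyClass:
    """Equivalence class of double traces under rotation, reversal and
    graph automorphism."""

    representative: DoubleTrace
    label: str
    size: int  # enumerated walks collapsed into this class
    symmetry_notes: str = ""

    @property
    def graph(self) -> PolyhedronGraph:
        return self.representative.graph


def _canonical_encoding(trace: DoubleTrace, automorphisms: list[dict]) -> tuple:
    graph = trace.graph
    index = {v: i for i, v in enumerate(graph.vertices)}
    L = trace.length
    seqs = []
    base = trace.vertex_sequence()
    for direction in (base, tuple(reversed(base))):
        for sigma in automorphisms:
            mapped = tuple(index[sigma[v]] for v in direction)
            for r in range(L):
                seqs.append(mapped[r:] + mapped[:r])
    return min(seqs)


def _trace_from_encoding(graph: PolyhedronGraph, enc: tuple) -> DoubleTrace:
    verts = graph.vertices
    seq = [verts[i] for i in enc]
    walk = tuple((seq[i], seq[(i + 1) % len(seq)]) for i in range(len(seq)))
    return DoubleTrace(graph, walk)


def group_topologies(traces: Sequence[DoubleTrace]) -> list[TopologyClass]:
    """Group traces into topology classes with reproducible labels.

    Classes are sorted by their canonical walk encoding, so labels
    "T1", "T2", ... are stable under re-runs.
    """
    if not traces:
        return []
    graph = traces[0].graph
    if any(t.graph != graph for t in traces):
        raise SchemaError("all traces must live on the same graph")
    autos = graph.automorphisms()
    buckets: dict = {}
    for t in traces:
        key = _canonical_encoding(t, autos)
        buckets.setdefault(key, []).append(t)
    classes = []
    for k, (key, members) in enumerate(sorted(buckets.items()), start=1):
        rep = _trace_from_encoding(graph, key)
        classes.append(
            TopologyClass(
                representative=rep,
                label=f"T{k}",
                size=len(members),
                symmetry_notes=(
                    f"{len(members)} enumerated walks collapse under "
                    f"{len(autos)} automorphisms x rotation x reversal"
                ),
            )
        )
    return classes


@dataclass(frozen=True)
class EdgeOrientationProfile:
    """Per-edge CC orientation implied by a double trace."""

    orientations: tuple  # tuple of (edge, 'parallel'|'antiparallel'), edge-sorted
    n_parallel: int
    n_antiparallel: int

    def orientation_of(self, edge) -> str:
        for e, o in self.orientations:
            if e == edge:
                return o
        raise KeyError(edge)


def edge_orientation_profile(trace: DoubleTrace) -> EdgeOrientationProfile:
    """Classify each edge: parallel when its two traversals run in the
    same direction, antiparallel when they oppose."""
    traversals: dict = {}
    for (u, v) in trace.walk:
        key = trace.graph.edge_key(u, v)
        traversals.setdefault(key, []).append((u, v))
    orient = []
    for e in trace.graph.edges:
        a, b = traversals[e]
        orient.append((e, PARALLEL if a == b else ANTIPARALLEL))
    n_par = sum(1 for _, o in orient if o == PARALLEL)
    return EdgeOrientationProfile(tuple(orient), n_par, len(orient) - n_par)


@dataclass(frozen=True)
class PermutationSlot:
    """One peptide-segment slot of a linearized chain."""

    edge: tuple
    edge_index: int
    direction: tuple  # (u, v) traversal; chain runs N->C along it
    partner_slot: int  # index of the other traversal of the same edge
    orientation: str  # CC orientation of the edge pair


@dataclass(frozen=True)
class CircularPermutation:
    """Linearization of a topology's canonical walk at a chosen start."""

    topology_label: str
    start_index: int  # 1-based
    slots: tuple  # tuple of PermutationSlot, length 2E
    graph: PolyhedronGraph = field(compare=False)

    @property
    def label(self) -> str:
        return f"{self.topology_label}.{self.start_index}"

    @property
    def n_slots(self) -> int:
        return len(self.slots)


def circular_permutations(topology: TopologyClass) -> list[CircularPermutation]:
    """All 2E circular permutations of a topology class, labelled
    "<label>.<k>" for start positions k = 1..2E along the canonical walk."""
    trace = topology.representative
    graph = trace.graph
    profile = edge_orientation_profile(trace)
    L = trace.length
    perms = []
    for k in range(L):
        steps = trace.walk[k:] + trace.walk[:k]
        edge_keys = [graph.edge_key(u, v) for (u, v) in steps]
        slots = []
        for i, (step, ekey) in enumerate(zip(steps, edge_keys)):
            partner = next(j for j in range(L) if j != i and edge_keys[j] == ekey)
            slots.append(
                PermutationSlot(
                    edge=ekey,
                    edge_index=graph.edges.index(ekey),
                    direction=step,
                    partner_slot=partner,
                    orientation=profile.orientation_of(ekey),
                )
            )
        perms.append(
            CircularPermutation(
                topology_label=topology.label,
                start_index=k + 1,
                slots=tuple(slots),
                graph=graph,
            )
        )
    return perms


@lru_cache(maxsize=None)
def tetrahedron_topologies() -> tuple:
    """The three proper strong double-trace classes of the tetrahedron."""
    g = PolyhedronGraph.named("tetrahedron")
    traces = enumerate_double_traces(g, require_proper=True, require_strong=True)
    return tuple(group_topologies(traces))


def topology_report(classes: Sequence[TopologyClass]) -> dict:
    """JSON-serializable report of topology classes and their permutations."""
    out = {"n_classes": len(classes), "classes": []}
    for cls in classes:
        profile = edge_orientation_profile(cls.representative)
        perms = circular_permutations(cls)
        out["classes"].append(
            {
                "label": cls.label,
                "walk_vertices": [str(v) for v in cls.representative.vertex_sequence()],
                "orientation_profile": {
                    "n_parallel": profile.n_parallel,
                    "n_antiparallel": profile.n_antiparallel,
                    "edges": [
                        {"edge": [str(u) for u in e], "orientation": o}
                        for e, o in profile.orientations
                    ],
                },
                "symmetry_notes": cls.symmetry_notes,
                "permutations": [
                    {
                        "label": p.label,
                        "slots": [
                            {
                                "edge": [str(u) for u in s.edge],
                                "direction": [str(u) for u in s.direction],
                                "partner_slot": s.partner_slot,
                                "orientation": s.orientation,
                            }
                            for s in p.slots
                        ],
                    }
                    for p in perms
                ],
            }
        )
    return out
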