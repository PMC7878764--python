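"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written against networkx primitives and
naive enumeration rather than the package's internal machinery: double
traces by unpruned directed-edge search, effective distances by explicit
simple-path enumeration on an explicitly built weighted graph, pathway
leaf censuses by plain recursion without memoization, and the folded
test by networkx component contraction plus isomorphism.
"""

from __future__ import annotations

import itertools

import networkx as nx

PAR = "parallel"
ANTI = "antiparallel"


# ---------------------------------------------------------------------------
# double traces


def naive_double_traces(vertices, edges, require_proper, require_strong):
    """All closed double traces as step tuples, from every start arc."""
    edges = [tuple(sorted(e)) for e in edges]
    adj = {v: [] for v in vertices}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    L = 2 * len(edges)
    results = []

    def extend(walk, counts):
        if len(walk) == L:
            if walk[-1][1] == walk[0][0]:
                wt = tuple(walk)
                if require_proper and not _proper(wt):
                    return
                if require_strong and not _strong(wt, vertices, edges):
                    return
                results.append(wt)
            return
        here = walk[-1][1]
        for nb in adj[here]:
            e = tuple(sorted((here, nb)))
            if counts.get(e, 0) >= 2:
                continue
            counts[e] = counts.get(e, 0) + 1
            walk.append((here, nb))
            extend(walk, counts)
            walk.pop()
            counts[e] -= 1

    for u, v in edges:
        for start in ((u, v), (v, u)):
            extend([start], {tuple(sorted(start)): 1})
    return results


def _proper(walk):
    L = len(walk)
    return all(
        tuple(sorted(walk[i])) != tuple(sorted(walk[(i + 1) % L])) for i in range(L)
    )


def _strong(walk, vertices, edges):
    L = len(walk)
    for v in vertices:
        incident = [e for e in edges if v in e]
        trans = nx.MultiGraph()
        trans.add_nodes_from(incident)
        for i in range(L):
            if walk[i][1] == v:
                e_in = tuple(sorted(walk[i]))
                e_out = tuple(sorted(walk[(i + 1) % L]))
                trans.add_edge(e_in, e_out)
        if trans.number_of_edges() != len(incident):
            return False
        if not nx.is_connected(trans):
            return False
    return True


def class_count(walks, vertices):
    """Number of equivalence classes under rotation/reversal/automorphism."""
    index = {v: i for i, v in enumerate(vertices)}
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for walk in walks:
        g.add_edges_from(tuple(sorted(s)) for s in walk)
    autos = list(
        nx.algorithms.isomorphism.GraphMatcher(g, g).isomorphisms_iter()
    )
    keys = set()
    for walk in walks:
        seq = tuple(u for u, _ in walk)
        best = None
        for direction in (seq, tuple(reversed(seq))):
            for sigma in autos:
                mapped = tuple(index[sigma[v]] for v in direction)
                for r in range(len(mapped)):
                    rot = mapped[r:] + mapped[:r]
                    if best is None or rot < best:
                        best = rot
        keys.add(best)
    return len(keys)


# ---------------------------------------------------------------------------
# effective chain graph, distances, steric filter


def build_graph(n_slots, formed):
    g = nx.Graph()
    for i in range(n_slots):
        g.add_edge(("N", i), ("C", i), weight=1)
    for i in range(n_slots - 1):
        g.add_edge(("C", i), ("N", i + 1), weight=0)
    for (i, j, geom) in formed:
        if geom == PAR:
            g.add_edge(("N", i), ("N", j), weight=0)
            g.add_edge(("C", i), ("C", j), weight=0)
        else:
            g.add_edge(("N", i), ("C", j), weight=0)
            g.add_edge(("C", i), ("N", j), weight=0)
    return g


def simple_path_distance(g, source, target):
    """Min total weight over ALL simple paths (exhaustive enumeration)."""
    if source == target:
        return 0
    best = None
    for path in nx.all_simple_paths(g, source, target):
        w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
        if best is None or w < best:
            best = w
    return best


def pair_distance(n_slots, formed, a, b, geom):
    g = build_graph(n_slots, formed)
    if geom == PAR:
        pairs = [(("N", a), ("N", b)), (("C", a), ("C", b))]
    else:
        pairs = [(("N", a), ("C", b)), (("C", a), ("N", b))]
    return min(simple_path_distance(g, s, t) for s, t in pairs)


def zero_components(n_slots, formed):
    g = build_graph(n_slots, formed)
    zero = nx.Graph()
    zero.add_nodes_from(g.nodes())
    zero.add_edges_from(
        (u, v) for u, v, d in g.edges(data=True) if d["weight"] == 0
    )
    comp = {}
    for k, nodes in enumerate(nx.connected_components(zero)):
        for node in nodes:
            comp[node] = k
    return comp


def steric_ok(n_slots, formed, a, b, geom):
    """Rigid-body rule: after adding the pair, every slot's termini must
    sit in distinct zero-weight components."""
    comp = zero_components(n_slots, list(formed) + [(a, b, geom)])
    return all(comp[("N", s)] != comp[("C", s)] for s in range(n_slots))


def folded(n_slots, formed, target_graph: nx.Graph):
    if 2 * len(formed) != n_slots:
        return False
    comp = zero_components(n_slots, formed)
    contracted = nx.MultiGraph()
    for (i, j, geom) in formed:
        if geom == PAR:
            e = (comp[("N", i)], comp[("C", i)])
        else:
            e = (comp[("N", i)], comp[("C", j)])
        contracted.add_edge(*e)
    if any(u == v for u, v in contracted.edges()):
        return False
    simple = nx.Graph(contracted)
    if simple.number_of_edges() != contracted.number_of_edges():
        return False
    if simple.number_of_nodes() != target_graph.number_of_nodes():
        return False
    return nx.is_isomorphic(simple, target_graph)


# ---------------------------------------------------------------------------
# pathway leaf census


def leaf_census_on_target(n_slots, candidates, on_target, formed=()):
    """(folded, total) leaves with the stricter on-target folded test."""
    formed = list(formed)
    paired = {s for (i, j, _) in formed for s in (i, j)}
    moves = []
    for (i, j, geom) in candidates:
        if i in paired or j in paired:
            continue
        if not steric_ok(n_slots, formed, i, j, geom):
            continue
        moves.append(((i, j, geom), pair_distance(n_slots, formed, i, j, geom)))
    if not moves:
        ok = {(i, j) for (i, j, _) in formed} == set(on_target)
        return (1 if ok else 0), 1
    dmin = min(d for _, d in moves)
    tot_f = tot_n = 0
    for (move, d) in moves:
        if d != dmin:
            continue
        f, n = leaf_census_on_target(n_slots, candidates, on_target, formed + [move])
        tot_f += f
        tot_n += n
    return tot_f, tot_n


def leaf_census(n_slots, candidates, target_graph, formed=()):
    """(folded, total) leaves by plain recursion over all event orders.

    ``candidates``: iterable of (i, j, geom) complementary slot pairs.
    """
    formed = list(formed)
    paired = {s for (i, j, _) in formed for s in (i, j)}
    moves = []
    for (i, j, geom) in candidates:
        if i in paired or j in paired:
            continue
        if not steric_ok(n_slots, formed, i, j, geom):
            continue
        moves.append(((i, j, geom), pair_distance(n_slots, formed, i, j, geom)))
    if not moves:
        is_folded = folded(n_slots, formed, target_graph)
        return (1 if is_folded else 0), 1
    dmin = min(d for _, d in moves)
    tot_f = tot_n = 0
    for (move, d) in moves:
        if d != dmin:
            continue
        f, n = leaf_census(n_slots, candidates, target_graph, formed + [move])
        tot_f += f
        tot_n += n
    return tot_f, tot_n
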