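"""Deterministic stepwise folding model and folding probability P_F.

At each folding step the complementary peptide pair with the shortest
effective intra-chain distance assembles into a CC dimer; distances are
then recalculated on the resulting intermediate.  When several pairs tie
at the minimum the pathway splits and every branch is examined.  Pairs
whose rigid-dimer geometry is sterically impossible in the current
intermediate are excluded.  A terminal state is *folded* when its formed
pairs, contracted so that each CC dimer becomes one edge and zero-cost
junctions merge into vertices, realize the target polyhedron; anything
else -- a wrong complete matching or a stuck state with free slots and
no admissible move -- is *misfolded*.

``P_F`` is the fraction of folding pathways (root-to-leaf paths of the
pathway tree) that end folded, computed with exact rational arithmetic.
Because the model does not say whether tied branches should be counted
per pathway or weighted equally per split, a probability-weighted
variant (each split sharing weight uniformly among its branches) is
reported alongside the primary leaf-census statistic.

Repeated modules make off-target pairings admissible moves; misfolding
is discovered by the tree, never forbidden a priori.  For a chain built
solely from unique cognate pairs every pathway ends in the target cage
and ``P_F = 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from ccpo.assembly import (
    Arrangement,
    FoldingState,
    ModuleLibrary,
    build_arrangement,
    _candidate_distance,
    _contracted_adjacency,
    _zero_components,
)
from ccpo.errors import (
    CCPOError,
    InfeasibleDesignError,
    MonotonicityError,
    NodeCapExceeded,
    SchemaError,
)
from ccpo.topology import (
    ANTIPARALLEL,
    PARALLEL,
    CircularPermutation,
    PolyhedronGraph,
    TopologyClass,
    circular_permutations,
)

FOLDED = "folded"
MISFOLDED = "misfolded"

DEFAULT_NODE_CAP = 10**6


# ---------------------------------------------------------------------------
# elementary moves


def _state_moves(state: FoldingState, steric_mode: str = "strict") -> list[tuple]:
    """[(slot pair, geometry, distance), ...] for all admissible moves."""
    comp = _zero_components(state)
    adj = _contracted_adjacency(state, comp)
    bfs_cache: dict = {}
    moves = []
    for (i, j, g) in state.free_candidates():
        if not _steric_ok(comp, state.n_slots, i, j, g, steric_mode):
            continue
        d = _cached_distance(comp, adj, bfs_cache, i, j, g)
        moves.append(((i, j), g, d))
    moves.sort(key=lambda m: m[0])
    return moves


def _steric_ok(comp: list, n_slots: int, a: int, b: int, geom: str, mode: str) -> bool:
    from ccpo.assembly import _steric_allowed_from_comp

    return _steric_allowed_from_comp(comp, n_slots, a, b, geom, mode)


def _cached_distance(comp, adj, bfs_cache, i, j, g):
    from ccpo.assembly import _bfs

    na, ca = comp[2 * i], comp[2 * i + 1]
    nb, cb = comp[2 * j], comp[2 * j + 1]
    for src in (na, ca):
        if src not in bfs_cache:
            bfs_cache[src] = _bfs(adj, src)
    if g == PARALLEL:
        options = (bfs_cache[na].get(nb), bfs_cache[ca].get(cb))
    else:
        options = (bfs_cache[na].get(cb), bfs_cache[ca].get(nb))
    options = [d for d in options if d is not None]
    return min(options)


def candidate_moves(state: FoldingState, steric_mode: str = "strict") -> list[tuple]:
    """All admissible formation events with their current distances.

    Returns ``[((i, j), distance), ...]`` over every complementary
    free-slot pair (on- and off-target, across copies) that passes the
    steric filter, in canonical slot order.
    """
    return [(pair, d) for pair, _, d in _state_moves(state, steric_mode)]


def expand(state: FoldingState, steric_mode: str = "strict") -> list[FoldingState]:
    """Successor states: one child per minimum-distance admissible move."""
    moves = _state_moves(state, steric_mode)
    if not moves:
        return []
    dmin = min(d for _, _, d in moves)
    return [state.form(*pair) for pair, _, d in moves if d == dmin]


# ---------------------------------------------------------------------------
# terminal classification


def contracted_structure(state: FoldingState) -> nx.MultiGraph:
    """Contract formed pairs to edges and zero-cost junctions to vertices."""
    comp = _zero_components(state)
    g = nx.MultiGraph()
    g.add_nodes_from(sorted(set(comp)))
    for (i, j, geom) in state.formed:
        if geom == PARALLEL:
            end1, end2 = comp[2 * i], comp[2 * i + 1]
        else:
            end1, end2 = comp[2 * i], comp[2 * j]  # N_i end merges with C_j
        g.add_edge(end1, end2, pair=(i, j))
    return g


def _is_folded(state: FoldingState, folded_mode: str) -> bool:
    if state.free_slots:
        return False
    if folded_mode == "on-target":
        return frozenset((i, j) for (i, j, _) in state.formed) == state.on_target
    if folded_mode != "structural":
        raise SchemaError(f"unknown folded mode {folded_mode!r}")
    target = state.target_graph
    if target is None:
        raise SchemaError("structural folded test requires a target graph")
    if len(state.formed) != target.n_edges:
        return False
    contracted = contracted_structure(state)
    used = {n for e in contracted.edges() for n in e}
    contracted = contracted.subgraph(used)
    if contracted.number_of_nodes() != len(target.vertices):
        return False
    if any(u == v for u, v in contracted.edges()):
        return False
    simple = nx.Graph(contracted)
    if simple.number_of_edges() != contracted.number_of_edges():
        return False  # doubled edge: not a simple polyhedron
    return nx.is_isomorphic(simple, target.to_networkx())


def classify_terminal(
    state: FoldingState,
    folded_mode: str = "structural",
    steric_mode: str = "strict",
) -> str:
    """Label a terminal state ``folded`` or ``misfolded``.

    A state is terminal when it admits no further formation event; calling
    this on a non-terminal state is a contract violation.
    """
    if _state_moves(state, steric_mode):
        raise CCPOError("classify_terminal called on a non-terminal state")
    return FOLDED if _is_folded(state, folded_mode) else MISFOLDED


# ---------------------------------------------------------------------------
# pathway tree and P_F


@dataclass
class PathwayNode:
    state: FoldingState
    move: Optional[tuple] = None  # ((i, j), distance) that produced this node
    label: Optional[str] = None  # set on leaves
    children: list = field(default_factory=list)


@dataclass
class PathwayTree:
    root: PathwayNode

    def leaves(self) -> list[PathwayNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.children:
                stack.extend(node.children)
            else:
                out.append(node)
        return out

    def to_dict(self) -> dict:
        def conv(node):
            d = {
                "formed": sorted((i, j) for (i, j, _) in node.state.formed),
                "move": list(node.move[0]) if node.move else None,
                "distance": node.move[1] if node.move else None,
            }
            if node.children:
                d["children"] = [conv(c) for c in node.children]
            else:
                d["label"] = node.label
            return d

        return conv(self.root)

    def to_dot(self) -> str:
        lines = ["digraph pathway {", "  node [shape=box];"]
        counter = itertools.count()

        def walk(node, nid):
            formed = ",".join(f"{i}-{j}" for (i, j, _) in sorted(node.state.formed))
            label = formed or "unfolded"
            if node.label:
                label += f"\\n{node.label}"
            color = {FOLDED: "green", MISFOLDED: "red"}.get(node.label, "black")
            lines.append(f'  n{nid} [label="{label}", color={color}];')
            for child in node.children:
                cid = next(counter)
                pair, dist = child.move
                lines.append(f'  n{nid} -> n{cid} [label="{pair[0]}-{pair[1]} (d={dist})"];')
                walk(child, cid)

        walk(self.root, next(counter))
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class FoldOutcome:
    """Folding statistics of one arrangement."""

    p_fold: Fraction
    folded_leaves: int
    total_leaves: int
    p_fold_weighted: Fraction  # uniform branch weights at every split
    n_states: int
    tree: Optional[PathwayTree] = None

    def __post_init__(self):
        if not 0 <= self.p_fold <= 1:
            raise CCPOError("P_F out of [0, 1]")


def folding_probability(
    source: Union[Arrangement, FoldingState],
    library: Optional[ModuleLibrary] = None,
    *,
    steric_mode: str = "strict",
    folded_mode: str = "structural",
    node_cap: int = DEFAULT_NODE_CAP,
    audit_monotonic: bool = False,
    build_tree: bool = False,
) -> FoldOutcome:
    """Expand the full pathway tree from the unfolded state and count.

    ``P_F = folded pathways / all pathways`` by exact rational leaf
    census; the uniform-branch-weight variant is reported alongside.
    Distinct formation orders reaching the same intermediate share one
    expansion (the model is Markovian in the set of formed pairs), so
    the census is computed by memoized recursion; ``node_cap`` bounds the
    number of distinct intermediates.  With ``audit_monotonic`` every
    expansion asserts that no surviving candidate's distance increased.
    """
    if isinstance(source, Arrangement):
        if library is None:
            raise SchemaError("folding_probability(arrangement) needs a library")
        root = FoldingState.from_arrangement(source, library)
    else:
        root = source

    memo: dict = {}

    def visit(state: FoldingState) -> tuple[int, int, Fraction]:
        key = state.formed
        if key in memo:
            return memo[key]
        if len(memo) >= node_cap:
            raise NodeCapExceeded(f"pathway expansion exceeded {node_cap} states")
        moves = _state_moves(state, steric_mode)
        if not moves:
            folded = _is_folded(state, folded_mode)
            res = (1 if folded else 0, 1, Fraction(1 if folded else 0))
        else:
            dmin = min(d for _, _, d in moves)
            winners = [(pair, g, d) for pair, g, d in moves if d == dmin]
            folded_leaves = total_leaves = 0
            weighted = Fraction(0)
            for pair, g, d in winners:
                child = state.form(*pair)
                if audit_monotonic:
                    _audit_child(state, child, moves, steric_mode)
                f, t, w = visit(child)
                folded_leaves += f
                total_leaves += t
                weighted += w
            res = (folded_leaves, total_leaves, weighted / len(winners))
        memo[key] = res
        return res

    folded, total, weighted = visit(root)
    tree = _build_tree(root, steric_mode, folded_mode) if build_tree else None
    return FoldOutcome(
        p_fold=Fraction(folded, total),
        folded_leaves=folded,
        total_leaves=total,
        p_fold_weighted=weighted,
        n_states=len(memo),
        tree=tree,
    )


def _audit_child(parent, child, parent_moves, steric_mode):
    parent_d = {pair: d for pair, _, d in parent_moves}
    for pair, _, d in _state_moves(child, steric_mode):
        if pair in parent_d and d > parent_d[pair]:
            raise MonotonicityError(
                f"distance of candidate {pair} rose {parent_d[pair]} -> {d} "
                f"after forming {child.formed - parent.formed}"
            )


def _build_tree(root, steric_mode, folded_mode) -> PathwayTree:
    def grow(state, move):
        node = PathwayNode(state=state, move=move)
        moves = _state_moves(state, steric_mode)
        if not moves:
            node.label = FOLDED if _is_folded(state, folded_mode) else MISFOLDED
            return node
        dmin = min(d for _, _, d in moves)
        for pair, g, d in moves:
            if d == dmin:
                node.children.append(grow(state.form(*pair), (pair, d)))
        return node

    return PathwayTree(root=grow(root, None))


# ---------------------------------------------------------------------------
# design search


def parse_module_multiset(spec: str) -> list[tuple]:
    """Parse "P3SN:P4SN x2, APHSN x2" into [(pair, count), ...].

    A pair is either a homodimer name or an ordered "A:B" heterodimer
    string; "xN" multiplies the number of cage edges the pair occupies.
    """
    out = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split()
        count = 1
        if len(parts) == 2 and parts[1].lower().startswith("x"):
            count = int(parts[1][1:])
        elif len(parts) != 1:
            raise SchemaError(f"bad multiset chunk {chunk!r}")
        pair = tuple(parts[0].split(":")) if ":" in parts[0] else parts[0]
        out.append((pair, count))
    return out


@dataclass
class DesignReport:
    """Ranked arrangements from an exhaustive design search."""

    entries: list  # dicts, sorted by P_F desc then canonical key
    search_space: dict

    @property
    def best(self) -> dict:
        return self.entries[0]

    @property
    def max_p_fold(self) -> Fraction:
        return self.entries[0]["p_fold"]

    def to_rows(self) -> list[dict]:
        return [
            {
                "permutation": e["permutation"],
                "assignment": e["assignment"],
                "p_fold_num": e["p_fold"].numerator,
                "p_fold_den": e["p_fold"].denominator,
                "folded_leaves": e["folded_leaves"],
                "total_leaves": e["total_leaves"],
            }
            for e in self.entries
        ]


def _pair_geometry(pair, library: ModuleLibrary) -> str:
    name = pair if isinstance(pair, str) else pair[0]
    return library[name].geometry


def _multiset_assignments(pairs_with_geom, edges_by_orientation):
    """Yield {edge: pair} maps placing the pair multiset onto the edges."""
    par_pairs = sorted(
        (p for p, g in pairs_with_geom if g == PARALLEL), key=str
    )
    anti_pairs = sorted(
        (p for p, g in pairs_with_geom if g == ANTIPARALLEL), key=str
    )
    par_edges = edges_by_orientation.get(PARALLEL, [])
    anti_edges = edges_by_orientation.get(ANTIPARALLEL, [])
    if len(par_pairs) != len(par_edges) or len(anti_pairs) != len(anti_edges):
        return
    def _key(order):
        return [str(p) for p in order]

    par_orders = sorted(set(itertools.permutations(par_pairs)), key=_key)
    anti_orders = sorted(set(itertools.permutations(anti_pairs)), key=_key)
    for par_order in par_orders:
        for anti_order in anti_orders:
            base = dict(zip(par_edges, par_order))
            base.update(zip(anti_edges, anti_order))
            yield base


def _orientation_choices(assignment):
    """Expand heterodimer (A, B) edges into both chain orders."""
    hetero_edges = [e for e, p in assignment.items() if not isinstance(p, str)]
    for flips in itertools.product((False, True), repeat=len(hetero_edges)):
        out = dict(assignment)
        for edge, flip in zip(hetero_edges, flips):
            a, b = assignment[edge]
            out[edge] = (b, a) if flip else (a, b)
        yield out


def design_search(
    targets: Sequence[Union[TopologyClass, CircularPermutation]],
    module_multiset: Union[str, Sequence[tuple]],
    library: ModuleLibrary,
    *,
    steric_mode: str = "strict",
    folded_mode: str = "structural",
    node_cap: int = DEFAULT_NODE_CAP,
    audit_monotonic: bool = False,
    keep: Optional[int] = None,
) -> DesignReport:
    """Exhaustively score arrangements of a module multiset on cage
    topologies.

    ``targets`` may mix topology classes (expanded to all their circular
    permutations) and individual permutations.  Every placement of the
    pair multiset onto geometry-compatible edges and every heterodimer
    chain order is enumerated; arrangements sharing an identical
    complementarity structure share one pathway-tree evaluation, since
    P_F depends only on which slots can pair and with what geometry.
    """
    if isinstance(module_multiset, str):
        module_multiset = parse_module_multiset(module_multiset)
    pairs_with_geom = []
    for pair, count in module_multiset:
        geom = _pair_geometry(pair, library)
        if not isinstance(pair, str):
            library.pair_names(pair)
        pairs_with_geom.extend([(pair, geom)] * count)

    permutations: list[CircularPermutation] = []
    for t in targets:
        if isinstance(t, TopologyClass):
            permutations.extend(circular_permutations(t))
        else:
            permutations.append(t)
    if not permutations:
        raise SchemaError("design_search needs at least one topology or permutation")

    demand = {
        PARALLEL: sum(1 for _, g in pairs_with_geom if g == PARALLEL),
        ANTIPARALLEL: sum(1 for _, g in pairs_with_geom if g == ANTIPARALLEL),
    }

    entries = []
    cache: dict = {}
    n_evaluated = 0
    feasible_perms = 0
    for perm in permutations:
        edges_by_orientation: dict = {}
        for meta in perm.slots:
            edges_by_orientation.setdefault(meta.orientation, [])
            if meta.edge not in edges_by_orientation[meta.orientation]:
                edges_by_orientation[meta.orientation].append(meta.edge)
        supply = {o: len(v) for o, v in edges_by_orientation.items()}
        if (
            demand[PARALLEL] != supply.get(PARALLEL, 0)
            or demand[ANTIPARALLEL] != supply.get(ANTIPARALLEL, 0)
        ):
            continue
        feasible_perms += 1
        for base in _multiset_assignments(pairs_with_geom, edges_by_orientation):
            for assignment in _orientation_choices(base):
                arrangement = build_arrangement(perm, assignment, library)
                state = FoldingState.from_arrangement(arrangement, library)
                sig = (state.n_slots, state.candidates)
                if sig in cache:
                    outcome = cache[sig]
                else:
                    outcome = folding_probability(
                        state,
                        steric_mode=steric_mode,
                        folded_mode=folded_mode,
                        node_cap=node_cap,
                        audit_monotonic=audit_monotonic,
                    )
                    cache[sig] = outcome
                n_evaluated += 1
                entries.append(
                    {
                        "permutation": perm.label,
                        "assignment": arrangement.assignment_string(),
                        "p_fold": outcome.p_fold,
                        "p_fold_weighted": outcome.p_fold_weighted,
                        "folded_leaves": outcome.folded_leaves,
                        "total_leaves": outcome.total_leaves,
                        "arrangement": arrangement,
                    }
                )
    if feasible_perms == 0:
        raise InfeasibleDesignError(
            f"module multiset demands {demand[PARALLEL]} parallel / "
            f"{demand[ANTIPARALLEL]} antiparallel edges; no requested "
            "permutation offers that orientation profile"
        )
    entries.sort(key=lambda e: (-e["p_fold"], e["permutation"], e["assignment"]))
    if keep is not None:
        entries = entries[:keep]
    return DesignReport(
        entries=entries,
        search_space={
            "n_permutations": len(permutations),
            "n_feasible_permutations": feasible_perms,
            "n_arrangements": n_evaluated,
            "n_unique_structures": len(cache),
            "module_multiset": [
                [list(p) if not isinstance(p, str) else p, c]
                for p, c in module_multiset
            ],
            "steric_mode": steric_mode,
            "folded_mode": folded_mode,
        },
    )
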