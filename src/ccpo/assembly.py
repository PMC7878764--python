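"""CC module libraries, chain arrangements and intra-chain distances.

A cage chain is a linear concatenation of 2E coiled-coil-forming peptide
*slots* joined by short linkers (GSGPG by default).  Complementary slots
dimerize; which pair forms next during folding is governed by the
*effective intra-chain distance*: the minimal number of peptide modules
separating the relevant termini of the two segments.  For parallel CCs
the distance is measured between matching termini (N-N or C-C), for
antiparallel CCs between opposing termini (N-C), taking the smaller of
the two pairings in either case.

Distances are shortest paths on the *effective chain graph*: every slot
contributes its N and C terminus as nodes joined by a weight-1 link
(crossing a module costs one), consecutive slots are joined by weight-0
linker links, and every formed CC pair adds weight-0 identification
links between the termini that the rigid dimer geometry superimposes
(parallel: N-N and C-C; antiparallel: N-C and C-N).  A formed pair is
thereby counted as a single segment, and distances can only shrink as
folding proceeds.

The steric filter treats a candidate dimer as a rigid rod: a candidate
is prohibited when termini that the dimer would place at *opposite* rod
ends are already connected at zero cost (the explicit special case being
parallel peptides positioned adjacently in the chain, whose assembly
would require a fold-back of zero-length linker).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import yaml

from ccpo.errors import GeometryError, SchemaError
from ccpo.topology import ANTIPARALLEL, PARALLEL, CircularPermutation, PolyhedronGraph

HOMODIMER = "homodimer"
HETERODIMER = "heterodimer"

DEFAULT_LINKER = "GSGPG"

# ---------------------------------------------------------------------------
# module library


@dataclass(frozen=True)
class CCModule:
    """One coiled-coil-forming peptide module.

    ``tm_C`` (melting temperature, deg C) and ``k_per_s`` (refolding rate,
    1/s) are informational metadata only; the folding model deliberately
    ignores module stability.
    """

    name: str
    geometry: str  # 'parallel' | 'antiparallel'
    pairing: str  # 'homodimer' | 'heterodimer'
    partner: str  # cognate module name; == name for homodimers
    sequence: Optional[str] = None
    tm_C: Optional[float] = None
    k_per_s: Optional[float] = None

    def __post_init__(self):
        if self.geometry not in (PARALLEL, ANTIPARALLEL):
            raise SchemaError(f"module {self.name!r}: bad geometry {self.geometry!r}")
        if self.pairing not in (HOMODIMER, HETERODIMER):
            raise SchemaError(f"module {self.name!r}: bad pairing {self.pairing!r}")
        if self.pairing == HOMODIMER and self.partner != self.name:
            raise SchemaError(f"homodimer {self.name!r} must partner itself")
        if self.pairing == HETERODIMER and self.partner == self.name:
            raise SchemaError(f"heterodimer {self.name!r} cannot partner itself")


class ModuleLibrary:
    """Set of CC modules with validated partner closure."""

    def __init__(self, modules: Iterable[CCModule]):
        mods = list(modules)
        names = [m.name for m in mods]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate module names: {dup}")
        self._modules = {m.name: m for m in mods}
        for m in mods:
            if m.partner not in self._modules:
                raise SchemaError(
                    f"module {m.name!r} references missing partner {m.partner!r}"
                )
            p = self._modules[m.partner]
            if p.partner != m.name:
                raise SchemaError(
                    f"partner closure violated: {m.name!r} -> {m.partner!r} -> {p.partner!r}"
                )
            if p.geometry != m.geometry:
                raise SchemaError(
                    f"geometry mismatch between partners {m.name!r} and {p.name!r}"
                )

    def __getitem__(self, name: str) -> CCModule:
        try:
            return self._modules[name]
        except KeyError:
            raise SchemaError(f"unknown module {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._modules

    def __iter__(self):
        return iter(self._modules.values())

    def __len__(self):
        return len(self._modules)

    @property
    def names(self) -> list[str]:
        return sorted(self._modules)

    def complementary(self, a: str, b: str) -> bool:
        """True when modules ``a`` and ``b`` can dimerize (cognate pair)."""
        return self[a].partner == b

    def pair_names(self, pair: Union[str, Sequence[str]]) -> tuple[str, str]:
        """Normalize a pair spec ("APHSN" or "P3SN:P4SN" or a 2-tuple)."""
        if isinstance(pair, str):
            parts = pair.split(":")
            if len(parts) == 1:
                a = b = parts[0]
            elif len(parts) == 2:
                a, b = parts
            else:
                raise SchemaError(f"bad pair spec {pair!r}")
        else:
            a, b = pair
        if not self.complementary(a, b):
            raise SchemaError(f"{a!r} and {b!r} are not a cognate pair")
        return a, b

    def to_dict(self) -> dict:
        return {
            "modules": [
                {
                    k: v
                    for k, v in {
                        "name": m.name,
                        "geometry": m.geometry,
                        "pairing": m.pairing,
                        "partner": m.partner,
                        "sequence": m.sequence,
                        "tm_C": m.tm_C,
                        "k_per_s": m.k_per_s,
                    }.items()
                    if v is not None
                }
                for m in sorted(self._modules.values(), key=lambda m: m.name)
            ]
        }


def load_library(source) -> ModuleLibrary:
    """Load a module library from a YAML/JSON file path, open file or dict."""
    data = _load_structured(source)
    if data is None:
        return ModuleLibrary([])
    entries = data.get("modules", data) if isinstance(data, dict) else data
    if entries in (None, {}):
        return ModuleLibrary([])
    mods = []
    for entry in entries:
        try:
            mods.append(
                CCModule(
                    name=entry["name"],
                    geometry=entry["geometry"],
                    pairing=entry["pairing"],
                    partner=entry.get("partner", entry["name"]),
                    sequence=entry.get("sequence"),
                    tm_C=entry.get("tm_C"),
                    k_per_s=entry.get("k_per_s"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"module entry missing field {exc}: {entry!r}") from None
    return ModuleLibrary(mods)


def dump_library(library: ModuleLibrary, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(library.to_dict(), fh, sort_keys=False)


def _load_structured(source):
    if isinstance(source, (dict, list)):
        return source
    if hasattr(source, "read"):
        return yaml.safe_load(source.read())
    with open(source) as fh:
        return yaml.safe_load(fh)


def _heptads(core: str, n: int = 4) -> str:
    return core * n


def sn_library() -> ModuleLibrary:
    """Built-in library mirroring the geometry/pairing pattern of the SN
    coiled-coil toolbox used for tetrahedral cages: four parallel
    heterodimer pairs, one parallel homodimer and two antiparallel
    homodimers.

    Sequences are synthetic placeholder heptad repeats (E/K-style acidic
    and basic helices), not the published peptides; they exist so that
    chain assembly produces defined-length FASTA output.
    """
    specs = [
        ("P3SN", PARALLEL, HETERODIMER, "P4SN", _heptads("EIQALEE")),
        ("P4SN", PARALLEL, HETERODIMER, "P3SN", _heptads("KIAQLKE")),
        ("P5SN", PARALLEL, HETERODIMER, "P6SN", _heptads("ENAALEQ")),
        ("P6SN", PARALLEL, HETERODIMER, "P5SN", _heptads("KNAALKQ")),
        ("P7SN", PARALLEL, HETERODIMER, "P8SN", _heptads("EIQALEQ")),
        ("P8SN", PARALLEL, HETERODIMER, "P7SN", _heptads("KIAQLKQ")),
        ("P9SN", PARALLEL, HETERODIMER, "P10SN", _heptads("EIAALEQ")),
        ("P10SN", PARALLEL, HETERODIMER, "P9SN", _heptads("KIAALKQ")),
        ("GCNSN", PARALLEL, HOMODIMER, "GCNSN", _heptads("MKQLEDK")),
        ("APHSN", ANTIPARALLEL, HOMODIMER, "APHSN", _heptads("ELKQLEE")),
        ("BCRSN", ANTIPARALLEL, HOMODIMER, "BCRSN", _heptads("DIEQELE")),
    ]
    return ModuleLibrary(
        CCModule(name=n, geometry=g, pairing=p, partner=pt, sequence=s)
        for n, g, p, pt, s in specs
    )


# ---------------------------------------------------------------------------
# arrangements


@dataclass(frozen=True)
class SlotAssignment:
    """A module instance occupying one chain slot."""

    module: str
    copy: int  # 1-based copy index among same-named instances


@dataclass(frozen=True)
class Arrangement:
    """Module-to-slot assignment on a linearized trace."""

    permutation: CircularPermutation
    slots: tuple  # tuple of SlotAssignment, length 2E
    linker: str = DEFAULT_LINKER
    on_target: tuple = ()  # slot-index pairs (i, j), i < j, one per edge

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def graph(self) -> PolyhedronGraph:
        return self.permutation.graph

    def assignment_string(self) -> str:
        return "-".join(f"{s.module}@{s.copy}" for s in self.slots)


def build_arrangement(
    permutation: CircularPermutation,
    assignment: Mapping,
    library: ModuleLibrary,
    linker: str = DEFAULT_LINKER,
) -> Arrangement:
    """Assign CC modules to the edges of a circular permutation.

    ``assignment`` maps an edge key (the vertex pair from the permutation's
    slots, or its edge index) to either a homodimer name or an ordered
    ``(first, second)`` heterodimer tuple: the first-named module occupies
    the earlier chain slot.  A bare heterodimer string without order is an
    ambiguity error; a module whose geometry contradicts the edge's trace
    orientation is a geometry error.  Repeated modules receive 1-based
    copy indices in chain order.
    """
    slots_meta = permutation.slots
    n = len(slots_meta)
    norm: dict = {}
    for key, value in assignment.items():
        if isinstance(key, int):
            edge = permutation.graph.edges[key]
        else:
            edge = permutation.graph.edge_key(*key)
        norm[edge] = value
    missing = [e for e in permutation.graph.edges if e not in norm]
    if missing:
        raise SchemaError(f"assignment missing edges: {missing}")

    chosen: dict = {}
    for i, meta in enumerate(slots_meta):
        j = meta.partner_slot
        if i > j:
            continue
        value = norm[meta.edge]
        if isinstance(value, str) and ":" in value:
            value = tuple(value.split(":"))
        if isinstance(value, str):
            first = second = value
            mod = library[value]
            if mod.pairing == HETERODIMER:
                raise SchemaError(
                    f"heterodimer {value!r} on edge {meta.edge} needs an ordered "
                    "(first, second) pair to fix which partner folds earlier"
                )
        else:
            first, second = value
            if not library.complementary(first, second):
                raise SchemaError(f"{first!r}:{second!r} is not a cognate pair")
        for name in (first, second):
            if library[name].geometry != meta.orientation:
                raise GeometryError(
                    f"{library[name].geometry} module {name!r} assigned to "
                    f"{meta.orientation} edge {meta.edge}"
                )
        chosen[i] = first
        chosen[j] = second

    counts: dict = {}
    slot_assignments = []
    for i in range(n):
        name = chosen[i]
        counts[name] = counts.get(name, 0) + 1
        slot_assignments.append(SlotAssignment(module=name, copy=counts[name]))

    on_target = tuple(
        sorted(
            tuple(sorted((i, meta.partner_slot)))
            for i, meta in enumerate(slots_meta)
            if i < meta.partner_slot
        )
    )
    return Arrangement(
        permutation=permutation,
        slots=tuple(slot_assignments),
        linker=linker,
        on_target=on_target,
    )


def assemble_sequence(
    arrangement: Arrangement,
    library: ModuleLibrary,
    include_tags: bool = False,
    name: Optional[str] = None,
):
    """Concatenate slot sequences with linkers into a single FASTA record.

    Output is ``slot1 + linker + slot2 + ... + slot2E`` (no trailing
    linker).  ``include_tags`` prepends an initiator methionine and
    appends a hexahistidine purification tag.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    missing = sorted(
        {s.module for s in arrangement.slots if library[s.module].sequence is None}
    )
    if missing:
        raise SchemaError(f"modules without sequences: {missing}")
    if arrangement.linker == "":
        warnings.warn("empty linker: slots concatenated directly", stacklevel=2)
    parts = [library[s.module].sequence for s in arrangement.slots]
    seq = arrangement.linker.join(parts)
    if include_tags:
        seq = "M" + seq + "LEHHHHHH"
    rec_name = name or f"{arrangement.permutation.label}_{arrangement.assignment_string()}"
    return SeqRecord(Seq(seq), id=rec_name, description="CCPO chain")


# ---------------------------------------------------------------------------
# folding states and the effective chain graph


@dataclass(frozen=True)
class FoldingState:
    """Partially folded chain: formed CC pairs plus remaining free slots.

    ``candidates`` lists every complementary slot pair with its CC
    geometry, independent of folding status; copies of a repeated module
    are interchangeable, so off-target cross-copy pairs are included.
    """

    n_slots: int
    candidates: tuple  # tuple of (i, j, geometry), i < j
    formed: frozenset = frozenset()  # frozenset of (i, j, geometry)
    on_target: frozenset = frozenset()  # frozenset of (i, j)
    target_graph: Optional[PolyhedronGraph] = None
    arrangement: Optional[Arrangement] = field(default=None, compare=False)

    @classmethod
    def from_arrangement(cls, arrangement: Arrangement, library: ModuleLibrary):
        n = arrangement.n_slots
        cands = []
        for i, j in itertools.combinations(range(n), 2):
            a = arrangement.slots[i].module
            b = arrangement.slots[j].module
            if library.complementary(a, b):
                cands.append((i, j, library[a].geometry))
        return cls(
            n_slots=n,
            candidates=tuple(cands),
            formed=frozenset(),
            on_target=frozenset(arrangement.on_target),
            target_graph=arrangement.graph,
            arrangement=arrangement,
        )

    def __post_init__(self):
        used: set = set()
        cand = {(i, j): g for i, j, g in self.candidates}
        for i, j, g in self.formed:
            if cand.get((i, j)) != g:
                raise SchemaError(f"formed pair ({i},{j},{g}) is not a valid candidate")
            if i in used or j in used:
                raise SchemaError("formed pairs must be disjoint")
            used.update((i, j))

    @property
    def paired_slots(self) -> frozenset:
        return frozenset(s for pair in self.formed for s in pair[:2])

    @property
    def free_slots(self) -> tuple:
        paired = self.paired_slots
        return tuple(s for s in range(self.n_slots) if s not in paired)

    def free_candidates(self) -> list[tuple]:
        paired = self.paired_slots
        return [
            (i, j, g)
            for (i, j, g) in self.candidates
            if i not in paired and j not in paired
        ]

    def geometry_of(self, a: int, b: int) -> str:
        i, j = min(a, b), max(a, b)
        for ci, cj, g in self.candidates:
            if (ci, cj) == (i, j):
                return g
        raise SchemaError(f"slots ({a}, {b}) are not complementary")

    def form(self, a: int, b: int) -> "FoldingState":
        i, j = min(a, b), max(a, b)
        g = self.geometry_of(i, j)
        return replace(self, formed=self.formed | {(i, j, g)})


# Terminus node ids in the fast path: N_i -> 2i, C_i -> 2i + 1.


def _zero_links(state: FoldingState) -> list[tuple[int, int]]:
    links = [(2 * i + 1, 2 * i + 2) for i in range(state.n_slots - 1)]  # linkers
    for (i, j, g) in state.formed:
        if g == PARALLEL:
            links.append((2 * i, 2 * j))
            links.append((2 * i + 1, 2 * j + 1))
        else:
            links.append((2 * i, 2 * j + 1))
            links.append((2 * i + 1, 2 * j))
    return links


def _zero_components(state: FoldingState) -> list[int]:
    """Union-find label per terminus node over the weight-0 sub-graph."""
    n = 2 * state.n_slots
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in _zero_links(state):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return [find(x) for x in range(n)]


def _contracted_adjacency(state: FoldingState, comp: list[int]) -> dict:
    """Contract zero components; each slot becomes a unit-cost link."""
    adj: dict = {}
    for i in range(state.n_slots):
        a, b = comp[2 * i], comp[2 * i + 1]
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _bfs(adj: dict, source: int) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def effective_graph(state: FoldingState) -> nx.Graph:
    """Weighted junction graph from which effective distances are read.

    Nodes are ("N", i) and ("C", i) termini of each slot; slot crossings
    weigh 1, linker links and formed-pair identifications weigh 0.
    """
    g = nx.Graph()
    for i in range(state.n_slots):
        g.add_edge(("N", i), ("C", i), weight=1, kind="segment")
    for i in range(state.n_slots - 1):
        g.add_edge(("C", i), ("N", i + 1), weight=0, kind="linker")
    for (i, j, geom) in state.formed:
        if geom == PARALLEL:
            g.add_edge(("N", i), ("N", j), weight=0, kind="pair")
            g.add_edge(("C", i), ("C", j), weight=0, kind="pair")
        else:
            g.add_edge(("N", i), ("C", j), weight=0, kind="pair")
            g.add_edge(("C", i), ("N", j), weight=0, kind="pair")
    return g


def intra_chain_distance(state: FoldingState, slot_a: int, slot_b: int) -> int:
    """Effective intra-chain distance between two complementary free slots.

    Parallel candidates take min over the N-N and C-C terminus pairings,
    antiparallel candidates min over N-C and C-N, each measured as the
    shortest path on the current effective chain graph.
    """
    a, b = min(slot_a, slot_b), max(slot_a, slot_b)
    paired = state.paired_slots
    if a in paired or b in paired:
        raise SchemaError(f"slots ({a}, {b}) are not both free")
    geom = state.geometry_of(a, b)
    comp = _zero_components(state)
    adj = _contracted_adjacency(state, comp)
    return _candidate_distance(comp, adj, a, b, geom)


def _candidate_distance(comp, adj, a: int, b: int, geom: str) -> int:
    na, ca = comp[2 * a], comp[2 * a + 1]
    nb, cb = comp[2 * b], comp[2 * b + 1]
    dist_n = _bfs(adj, na)
    dist_c = _bfs(adj, ca)
    if geom == PARALLEL:
        options = (dist_n.get(nb), dist_c.get(cb))
    else:
        options = (dist_n.get(cb), dist_c.get(nb))
    options = [d for d in options if d is not None]
    if not options:
        raise SchemaError("termini not connected in effective chain graph")
    return min(options)


def _pair_ids(a: int, b: int, geom: str) -> tuple:
    if geom == PARALLEL:
        return ((2 * a, 2 * b), (2 * a + 1, 2 * b + 1))
    return ((2 * a, 2 * b + 1), (2 * a + 1, 2 * b))


def _steric_allowed_from_comp(
    comp: list, n_slots: int, a: int, b: int, geom: str, mode: str
) -> bool:
    if mode == "adjacency-only":
        return not (geom == PARALLEL and abs(a - b) == 1)
    na, ca = comp[2 * a], comp[2 * a + 1]
    nb, cb = comp[2 * b], comp[2 * b + 1]
    end1, end2 = ((na, nb), (ca, cb)) if geom == PARALLEL else ((na, cb), (ca, nb))
    if any(x == y for x in end1 for y in end2):
        return False
    if mode == "candidate-only":
        return True
    if mode != "strict":
        raise SchemaError(f"unknown steric mode {mode!r}")
    # Rigid-body closure test: merge in the candidate's identification
    # links and require every segment (and hence every dimer) to keep its
    # two ends at distinct zero-cost junctions.
    alias: dict = {}

    def find(x):
        while x in alias:
            x = alias[x]
        return x

    for x, y in _pair_ids(a, b, geom):
        rx, ry = find(comp[x]), find(comp[y])
        if rx != ry:
            alias[rx] = ry
    for s in range(n_slots):
        if find(comp[2 * s]) == find(comp[2 * s + 1]):
            return False
    return True


def steric_allowed(
    state: FoldingState, slot_a: int, slot_b: int, mode: str = "strict"
) -> bool:
    """Whether a rigid CC dimer between two free complementary slots can
    physically form in the current intermediate.

    ``strict`` (default) treats every peptide segment as a rigid body of
    nonzero length: the event is prohibited when, once the dimer's
    zero-weight identification links are added, some segment's N and C
    termini would be joined by a zero-weight path -- the segment would
    have to start and end at the same point in space.  This subsumes the
    pre-formation opposite-end test (a candidate whose opposite rod ends
    are already zero-connected fails it) and in particular prohibits
    parallel candidates on chain-adjacent slots, while leaving
    antiparallel hairpins of adjacent slots allowed.

    ``candidate-only`` applies only the pre-formation opposite-end test
    of the candidate itself; ``adjacency-only`` prohibits nothing but
    chain-adjacent parallel candidates.
    """
    a, b = min(slot_a, slot_b), max(slot_a, slot_b)
    geom = state.geometry_of(a, b)
    comp = _zero_components(state)
    return _steric_allowed_from_comp(comp, state.n_slots, a, b, geom, mode)
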