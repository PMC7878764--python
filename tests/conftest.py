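"""Shared fixtures: module libraries, cage topologies and random small
arrangements for oracle cross-checks."""

from __future__ import annotations

import random

import pytest

from ccpo.assembly import (
    ANTIPARALLEL,
    HETERODIMER,
    HOMODIMER,
    PARALLEL,
    CCModule,
    FoldingState,
    ModuleLibrary,
    build_arrangement,
    sn_library,
)
from ccpo.topology import (
    PolyhedronGraph,
    circular_permutations,
    enumerate_double_traces,
    group_topologies,
    tetrahedron_topologies,
)


@pytest.fixture(scope="session")
def sn_lib():
    return sn_library()


@pytest.fixture(scope="session")
def tet_classes():
    return list(tetrahedron_topologies())


@pytest.fixture(scope="session")
def mini_lib():
    """Small mixed library: parallel hetero/homo, antiparallel hetero/homo."""
    def het(a, b, geom):
        return [
            CCModule(a, geom, HETERODIMER, b, sequence="A" * 21),
            CCModule(b, geom, HETERODIMER, a, sequence="A" * 21),
        ]

    mods = het("P1", "P2", PARALLEL) + het("Q1", "Q2", PARALLEL)
    mods += het("Z1", "Z2", ANTIPARALLEL)
    mods.append(CCModule("HP", PARALLEL, HOMODIMER, "HP", sequence="A" * 21))
    mods.append(CCModule("X", ANTIPARALLEL, HOMODIMER, "X", sequence="A" * 21))
    mods.append(CCModule("Y", ANTIPARALLEL, HOMODIMER, "Y", sequence="A" * 21))
    return ModuleLibrary(mods)


@pytest.fixture(scope="session")
def small_topologies():
    """Proper+strong topology classes of small cage graphs (<= 8 slots)."""
    out = {}
    for name, (verts, edges) in {
        "C3": ((0, 1, 2), ((0, 1), (1, 2), (0, 2))),
        "C4": ((0, 1, 2, 3), ((0, 1), (1, 2), (2, 3), (0, 3))),
    }.items():
        g = PolyhedronGraph(verts, edges)
        traces = enumerate_double_traces(g, require_proper=True, require_strong=True)
        out[name] = group_topologies(traces)
    return out


@pytest.fixture(scope="session")
def random_arrangement(small_topologies, mini_lib):
    """Factory: seeded random small arrangement, repeats allowed."""
    par_types = [("P1", "P2"), ("Q1", "Q2"), "HP"]
    anti_types = [("Z1", "Z2"), "X", "Y"]

    def make(seed: int):
        rng = random.Random(seed)
        name = rng.choice([k for k, v in small_topologies.items() if v])
        cls = rng.choice(small_topologies[name])
        perm = rng.choice(circular_permutations(cls))
        assignment = {}
        for meta in perm.slots:
            if meta.edge in assignment:
                continue
            pool = par_types if meta.orientation == PARALLEL else anti_types
            choice = rng.choice(pool)
            if isinstance(choice, tuple) and rng.random() < 0.5:
                choice = (choice[1], choice[0])
            assignment[meta.edge] = choice
        return build_arrangement(perm, assignment, mini_lib)

    return make


def unique_assignment_for(perm, rng: random.Random):
    """Random assignment of fresh unique cognate pairs to every edge of a
    permutation (orthogonal modules, no repeats); returns (library,
    assignment).  Pairing type (hetero/homodimer) and heterodimer chain
    orientation are randomized."""
    mods, assignment = [], {}
    edges = []
    for meta in perm.slots:
        if meta.edge not in edges:
            edges.append(meta.edge)
    for k, meta_edge in enumerate(edges):
        orientation = next(m.orientation for m in perm.slots if m.edge == meta_edge)
        if rng.random() < 0.5:
            a, b = f"U{k}a", f"U{k}b"
            mods.append(CCModule(a, orientation, HETERODIMER, b, sequence="A" * 21))
            mods.append(CCModule(b, orientation, HETERODIMER, a, sequence="A" * 21))
            assignment[meta_edge] = (a, b) if rng.random() < 0.5 else (b, a)
        else:
            h = f"U{k}h"
            mods.append(CCModule(h, orientation, HOMODIMER, h, sequence="A" * 21))
            assignment[meta_edge] = h
    return ModuleLibrary(mods), assignment
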