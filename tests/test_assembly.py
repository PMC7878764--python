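"""Module libraries, arrangements, sequences and intra-chain distances."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ccpo.assembly import (
    ANTIPARALLEL,
    PARALLEL,
    CCModule,
    FoldingState,
    ModuleLibrary,
    assemble_sequence,
    build_arrangement,
    effective_graph,
    intra_chain_distance,
    load_library,
    sn_library,
    steric_allowed,
)
from ccpo.errors import GeometryError, SchemaError
from ccpo.topology import circular_permutations
from conftest import unique_assignment_for


class TestLibrary:
    def test_sn_roster_pattern(self, sn_lib):
        hetero_par = [m for m in sn_lib
                      if m.pairing == "heterodimer" and m.geometry == PARALLEL]
        assert len(hetero_par) == 8  # four parallel heterodimer pairs
        assert sn_lib["GCNSN"].pairing == "homodimer"
        assert sn_lib["APHSN"].geometry == ANTIPARALLEL
        assert sn_lib["BCRSN"].geometry == ANTIPARALLEL
        assert sn_lib.complementary("P3SN", "P4SN")
        assert not sn_lib.complementary("P3SN", "P6SN")

    def test_dangling_partner_rejected(self):
        with pytest.raises(SchemaError, match="missing partner"):
            ModuleLibrary([CCModule("A", PARALLEL, "heterodimer", "GHOST")])

    def test_partner_closure_and_geometry_validated(self):
        a = CCModule("A", PARALLEL, "heterodimer", "B")
        b_wrong = CCModule("B", PARALLEL, "heterodimer", "C")
        c = CCModule("C", PARALLEL, "heterodimer", "B")
        with pytest.raises(SchemaError, match="closure"):
            ModuleLibrary([a, b_wrong, c])
        b_geom = CCModule("B", ANTIPARALLEL, "heterodimer", "A")
        with pytest.raises(SchemaError):
            ModuleLibrary([a, b_geom])

    def test_duplicate_names_rejected(self):
        m = CCModule("A", PARALLEL, "homodimer", "A")
        with pytest.raises(SchemaError, match="duplicate"):
            ModuleLibrary([m, m])

    def test_empty_and_roundtrip(self, tmp_path, sn_lib):
        empty = tmp_path / "empty.yaml"
        empty.write_text("")
        assert len(load_library(empty)) == 0
        path = tmp_path / "lib.yaml"
        from ccpo.assembly import dump_library

        dump_library(sn_lib, path)
        again = load_library(path)
        assert again.names == sn_lib.names
        assert again["P5SN"] == sn_lib["P5SN"]


class TestArrangement:
    def test_geometry_mismatch_is_an_error(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        par_edges = sorted({m.edge for m in perm.slots if m.orientation == PARALLEL})
        anti_edges = sorted({m.edge for m in perm.slots if m.orientation == ANTIPARALLEL})
        bad = {par_edges[0]: "APHSN"}  # antiparallel homodimer on parallel edge
        bad.update({e: ("P3SN", "P4SN") for e in par_edges[1:]})
        bad.update(dict(zip(anti_edges, ["APHSN", "BCRSN"])))
        with pytest.raises(GeometryError):
            build_arrangement(perm, bad, sn_lib)

    def test_heterodimer_needs_orientation(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        assignment = {m.edge: ("P3SN", "P4SN") if m.orientation == PARALLEL else "APHSN"
                      for m in perm.slots}
        first_par = next(m.edge for m in perm.slots if m.orientation == PARALLEL)
        assignment[first_par] = "P3SN:P4SN"  # string form carries the order
        arr = build_arrangement(perm, assignment, sn_lib)
        assignment[first_par] = "P3SN"  # bare heterodimer name is ambiguous
        with pytest.raises(SchemaError, match="ordered"):
            build_arrangement(perm, assignment, sn_lib)

    def test_copy_indices_count_repeats_in_chain_order(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        par_edges = sorted({m.edge for m in perm.slots if m.orientation == PARALLEL})
        anti_edges = sorted({m.edge for m in perm.slots if m.orientation == ANTIPARALLEL})
        assignment = {
            par_edges[0]: ("P3SN", "P4SN"),
            par_edges[1]: ("P5SN", "P6SN"),
            par_edges[2]: ("P5SN", "P6SN"),
            par_edges[3]: ("P7SN", "P8SN"),
            anti_edges[0]: "APHSN",
            anti_edges[1]: "BCRSN",
        }
        arr = build_arrangement(perm, assignment, sn_lib)
        p5_copies = [s.copy for s in arr.slots if s.module == "P5SN"]
        assert sorted(p5_copies) == [1, 2]
        aph_copies = [s.copy for s in arr.slots if s.module == "APHSN"]
        assert sorted(aph_copies) == [1, 2]


class TestSequenceAssembly:
    def test_length_closed_form(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        rng = random.Random(7)
        lib, assignment = unique_assignment_for(perm, rng)
        arr = build_arrangement(perm, assignment, lib)
        rec = assemble_sequence(arr, lib)
        assert len(rec.seq) == 12 * 21 + 11 * 5

    def test_empty_linker_warns(self, tet_classes):
        perm = circular_permutations(tet_classes[0])[0]
        lib, assignment = unique_assignment_for(perm, random.Random(3))
        arr = build_arrangement(perm, assignment, lib, linker="")
        with pytest.warns(UserWarning, match="empty linker"):
            rec = assemble_sequence(arr, lib)
        assert len(rec.seq) == 12 * 21

    def test_missing_sequences_reported(self, tet_classes):
        perm = circular_permutations(tet_classes[0])[0]
        lib, assignment = unique_assignment_for(perm, random.Random(3))
        from dataclasses import replace

        from ccpo.assembly import ModuleLibrary

        stripped = ModuleLibrary(replace(m, sequence=None) for m in lib)
        arr = build_arrangement(perm, assignment, stripped)
        with pytest.raises(SchemaError, match="without sequences"):
            assemble_sequence(arr, stripped)


def _abstract_state(n, candidates, formed=()):
    return FoldingState(
        n_slots=n,
        candidates=tuple(candidates),
        formed=frozenset(formed),
    )


class TestEffectiveGraph:
    def test_unfolded_chain_is_a_path(self):
        state = _abstract_state(12, [(2, 7, PARALLEL)])
        g = effective_graph(state)
        assert g.number_of_nodes() == 24
        ones = [e for e in g.edges(data=True) if e[2]["weight"] == 1]
        zeros = [e for e in g.edges(data=True) if e[2]["weight"] == 0]
        assert len(ones) == 12 and len(zeros) == 11
        assert nx.is_connected(g)

    def test_formed_pair_adds_zero_identifications(self):
        state = _abstract_state(12, [(2, 7, PARALLEL)], [(2, 7, PARALLEL)])
        g = effective_graph(state)
        assert g[("N", 2)][("N", 7)]["weight"] == 0
        assert g[("C", 2)][("C", 7)]["weight"] == 0

    def test_unfolded_distance_closed_forms(self):
        # parallel candidates at gap g have distance g, antiparallel g - 1
        for (i, j) in [(0, 1), (2, 7), (3, 9), (0, 11)]:
            par = _abstract_state(12, [(i, j, PARALLEL)])
            anti = _abstract_state(12, [(i, j, ANTIPARALLEL)])
            assert intra_chain_distance(par, i, j) == j - i
            assert intra_chain_distance(anti, i, j) == j - i - 1

    def test_formed_hairpin_shortens_spanning_candidate(self):
        # antiparallel candidate (1, 6) spans a formed hairpin (3, 4); the
        # hairpin's outer termini (N3, C4) are identified, so the chain
        # passes its turn end at zero cost: 4 intervening crossings drop
        # to 2 (values audited by the simple-path enumeration oracle)
        cands = [(1, 6, ANTIPARALLEL), (3, 4, ANTIPARALLEL)]
        before = _abstract_state(8, cands)
        after = _abstract_state(8, cands, [(3, 4, ANTIPARALLEL)])
        assert intra_chain_distance(before, 1, 6) == 4
        assert intra_chain_distance(after, 1, 6) == 2
        assert intra_chain_distance(after, 1, 6) == oracles.pair_distance(
            8, after.formed, 1, 6, ANTIPARALLEL
        )

    def test_pair_counts_as_one_segment(self):
        # crossing either member of a formed parallel pair costs one
        cands = [(2, 7, PARALLEL), (0, 9, PARALLEL)]
        state = _abstract_state(10, cands, [(2, 7, PARALLEL)])
        assert intra_chain_distance(state, 0, 9) == 4  # 0->2, jump to 7, ->9

    def test_distance_requires_free_complementary_slots(self):
        state = _abstract_state(6, [(0, 3, PARALLEL)], [(0, 3, PARALLEL)])
        with pytest.raises(SchemaError):
            intra_chain_distance(state, 0, 3)
        with pytest.raises(SchemaError):
            intra_chain_distance(_abstract_state(6, []), 1, 4)


class TestStericFilter:
    def test_adjacent_parallel_prohibited_antiparallel_allowed(self):
        par = _abstract_state(6, [(2, 3, PARALLEL)])
        anti = _abstract_state(6, [(2, 3, ANTIPARALLEL)])
        assert not steric_allowed(par, 2, 3)
        assert steric_allowed(anti, 2, 3)
        # one intervening module is enough for a parallel pair
        gap2 = _abstract_state(6, [(2, 4, PARALLEL)])
        assert steric_allowed(gap2, 2, 4)

    def test_gap_two_antiparallel_traps_middle_segment(self):
        state = _abstract_state(6, [(2, 4, ANTIPARALLEL)])
        assert not steric_allowed(state, 2, 4, mode="strict")
        # the candidate itself passes the weaker pre-formation test
        assert steric_allowed(state, 2, 4, mode="candidate-only")

    def test_adjacency_only_mode(self):
        par = _abstract_state(6, [(2, 3, PARALLEL)])
        anti_gap2 = _abstract_state(6, [(2, 4, ANTIPARALLEL)])
        assert not steric_allowed(par, 2, 3, mode="adjacency-only")
        assert steric_allowed(anti_gap2, 2, 4, mode="adjacency-only")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_distances_match_simple_path_enumeration(self, seed, random_arrangement,
                                                     mini_lib):
        arr = random_arrangement(seed)
        state = FoldingState.from_arrangement(arr, mini_lib)
        rng = random.Random(seed)
        # walk a few random formation events, checking every free candidate
        for _ in range(3):
            free = state.free_candidates()
            for (i, j, geom) in free:
                assert intra_chain_distance(state, i, j) == oracles.pair_distance(
                    state.n_slots, state.formed, i, j, geom
                )
                assert steric_allowed(state, i, j) == oracles.steric_ok(
                    state.n_slots, state.formed, i, j, geom
                )
            if not free:
                break
            state = state.form(*rng.choice(free)[:2])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_distance_monotone_under_formation(self, seed):
        """Adding any formation event never increases any candidate's
        distance (only zero-weight links are added)."""
        rng = random.Random(seed)
        n = rng.choice([6, 8])
        slots = list(range(n))
        rng.shuffle(slots)
        cands = []
        while len(slots) >= 2:
            i, j = sorted((slots.pop(), slots.pop()))
            cands.append((i, j, rng.choice([PARALLEL, ANTIPARALLEL])))
        state = _abstract_state(n, cands)
        order = list(cands)
        rng.shuffle(order)
        for move in order:
            before = {
                (i, j): intra_chain_distance(state, i, j)
                for (i, j, _) in state.free_candidates()
                if (i, j) != move[:2]
            }
            state = state.form(move[0], move[1])
            for (i, j, _) in state.free_candidates():
                assert intra_chain_distance(state, i, j) <= before[(i, j)]
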