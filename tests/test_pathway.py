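"""Stepwise folding model: moves, tie splitting, P_F, design search."""

import random
from fractions import Fraction

import pytest

import oracles
from ccpo.assembly import ANTIPARALLEL, PARALLEL, FoldingState
from ccpo.errors import CCPOError, InfeasibleDesignError, NodeCapExceeded
from ccpo.pathway import (
    candidate_moves,
    classify_terminal,
    contracted_structure,
    design_search,
    expand,
    folding_probability,
    parse_module_multiset,
)
from ccpo.topology import circular_permutations
from conftest import unique_assignment_for
from ccpo.assembly import build_arrangement


def _abstract(n, cands, formed=(), target=None, on_target=()):
    return FoldingState(
        n_slots=n,
        candidates=tuple(cands),
        formed=frozenset(formed),
        on_target=frozenset(on_target),
        target_graph=target,
    )


@pytest.fixture()
def unique_tet(tet_classes):
    perm = circular_permutations(tet_classes[0])[0]
    lib, assignment = unique_assignment_for(perm, random.Random(11))
    arr = build_arrangement(perm, assignment, lib)
    return arr, lib


class TestCandidateMoves:
    def test_unique_tetrahedron_has_one_candidate_per_edge(self, unique_tet):
        arr, lib = unique_tet
        state = FoldingState.from_arrangement(arr, lib)
        moves = candidate_moves(state)
        assert len(moves) == 6
        assert {pair for pair, _ in moves} == set(arr.on_target)

    def test_duplicated_pair_generates_cross_copy_candidates(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        par = sorted({m.edge for m in perm.slots if m.orientation == PARALLEL})
        anti = sorted({m.edge for m in perm.slots if m.orientation == ANTIPARALLEL})
        assignment = {
            par[0]: ("P3SN", "P4SN"), par[1]: ("P5SN", "P6SN"),
            par[2]: ("P5SN", "P6SN"), par[3]: ("P7SN", "P8SN"),
            anti[0]: "APHSN", anti[1]: "BCRSN",
        }
        arr = build_arrangement(perm, assignment, sn_lib)
        state = FoldingState.from_arrangement(arr, sn_lib)
        # two P5 copies x two P6 copies = 4 candidates for that pair type
        assert len(state.candidates) == 4 + 4  # 4 unique pairs + 4 cross-copy
        assert len(candidate_moves(state)) >= 6

    def test_fully_paired_state_has_no_moves(self, unique_tet):
        arr, lib = unique_tet
        state = FoldingState.from_arrangement(arr, lib)
        for (i, j) in sorted(arr.on_target):
            state = state.form(i, j)
        assert candidate_moves(state) == []


class TestExpand:
    def test_single_minimum_gives_one_child(self):
        state = _abstract(6, [(0, 3, PARALLEL), (1, 5, PARALLEL)])
        children = expand(state)
        assert len(children) == 1
        assert {(0, 3, PARALLEL)} == set(children[0].formed)

    def test_ties_split_the_pathway(self):
        cands = [(0, 3, PARALLEL), (2, 5, PARALLEL), (4, 7, PARALLEL)]
        state = _abstract(8, cands)
        children = expand(state)
        assert len(children) == 3  # three pairs tie at distance 3

    def test_children_recompute_distances(self):
        cands = [(0, 3, PARALLEL), (1, 6, ANTIPARALLEL)]
        state = _abstract(8, cands)
        d_before = dict(candidate_moves(state))
        child = expand(state)[0]
        d_after = dict(candidate_moves(child))
        for pair, d in d_after.items():
            assert d <= d_before[pair]


class TestTerminalClassification:
    def test_on_target_completion_is_folded(self, unique_tet):
        arr, lib = unique_tet
        state = FoldingState.from_arrangement(arr, lib)
        for (i, j) in sorted(arr.on_target):
            state = state.form(i, j)
        assert classify_terminal(state) == "folded"
        assert classify_terminal(state, folded_mode="on-target") == "folded"

    def test_non_terminal_state_is_a_contract_violation(self, unique_tet):
        arr, lib = unique_tet
        state = FoldingState.from_arrangement(arr, lib)
        with pytest.raises(CCPOError, match="non-terminal"):
            classify_terminal(state)

    def test_wrong_matching_contracts_to_non_tetrahedron(self, tet_classes, sn_lib):
        perm = circular_permutations(tet_classes[0])[0]
        par = sorted({m.edge for m in perm.slots if m.orientation == PARALLEL})
        anti = sorted({m.edge for m in perm.slots if m.orientation == ANTIPARALLEL})
        assignment = {
            par[0]: ("P3SN", "P4SN"), par[1]: ("P5SN", "P6SN"),
            par[2]: ("P5SN", "P6SN"), par[3]: ("P7SN", "P8SN"),
            anti[0]: "APHSN", anti[1]: "BCRSN",
        }
        arr = build_arrangement(perm, assignment, sn_lib)
        state = FoldingState.from_arrangement(arr, sn_lib)
        p5 = sorted(i for i, s in enumerate(arr.slots) if s.module == "P5SN")
        p6 = sorted(i for i, s in enumerate(arr.slots) if s.module == "P6SN")
        swapped = {tuple(sorted((p5[0], p6[1]))), tuple(sorted((p5[1], p6[0])))}
        matching = swapped | {
            (i, j) for (i, j) in arr.on_target
            if not {i, j} & set(p5 + p6)
        }
        for (i, j) in sorted(matching):
            state = state.form(i, j)
        # independent oracle agrees on the structural verdict
        target_nx = arr.graph.to_networkx()
        expect = oracles.folded(state.n_slots, state.formed, target_nx)
        got = classify_terminal(state) == "folded" if not candidate_moves(state) else None
        if got is not None:
            assert got == expect

    def test_stuck_state_is_misfolded(self):
        # two free antiparallel slots at gap 2: only candidate is blocked
        cands = [(1, 3, ANTIPARALLEL)]
        state = _abstract(5, cands)
        assert candidate_moves(state) == []
        assert classify_terminal(state) == "misfolded"


class TestFoldingProbability:
    def test_unique_arrangements_fold_with_certainty(self, tet_classes):
        rng = random.Random(2024)
        for cls in tet_classes:
            perm = rng.choice(circular_permutations(cls))
            lib, assignment = unique_assignment_for(perm, rng)
            arr = build_arrangement(perm, assignment, lib)
            out = folding_probability(arr, lib, audit_monotonic=True)
            assert out.p_fold == 1
            assert out.p_fold_weighted == 1
            assert out.folded_leaves == out.total_leaves

    def test_two_slot_hairpin_single_pathway(self, mini_lib):
        state = _abstract(2, [(0, 1, ANTIPARALLEL)], on_target=[(0, 1)])
        out = folding_probability(state, folded_mode="on-target", build_tree=True)
        assert out.p_fold == 1
        assert out.total_leaves == 1
        assert out.tree.root.children[0].label == "folded"

    def test_bad_repeat_order_loses_pathways(self):
        # one heterodimer type on three edges, interleaved so that
        # off-target pairings compete; exact value frozen from the
        # exhaustive tree, cross-checked by the naive recursion oracle
        geoms = {}
        cands = []
        a_slots = [0, 2, 4]
        b_slots = [1, 3, 5]
        for i in a_slots:
            for j in b_slots:
                pair = tuple(sorted((i, j)))
                cands.append((pair[0], pair[1], PARALLEL))
        on_target = [(0, 1), (2, 3), (4, 5)]
        state = _abstract(6, cands, on_target=on_target)
        out = folding_probability(state, folded_mode="on-target")
        f, n = oracles.leaf_census_on_target(6, cands, set(on_target))
        assert (out.folded_leaves, out.total_leaves) == (f, n)
        assert out.p_fold < 1

    def test_node_cap_raises(self, unique_tet):
        arr, lib = unique_tet
        with pytest.raises(NodeCapExceeded):
            folding_probability(arr, lib, node_cap=3)

    def test_deterministic_outcome(self, unique_tet):
        arr, lib = unique_tet
        a = folding_probability(arr, lib, build_tree=True)
        b = folding_probability(arr, lib, build_tree=True)
        assert a.p_fold == b.p_fold == Fraction(1)
        assert a.tree.to_dict() == b.tree.to_dict()

    @pytest.mark.parametrize("seed", range(12))
    def test_leaf_census_matches_naive_recursion(self, seed, random_arrangement,
                                                 mini_lib):
        arr = random_arrangement(seed)
        state = FoldingState.from_arrangement(arr, mini_lib)
        out = folding_probability(state, audit_monotonic=True)
        f, n = oracles.leaf_census(
            state.n_slots, state.candidates, arr.graph.to_networkx()
        )
        assert (out.folded_leaves, out.total_leaves) == (f, n)

    def test_unique_replacement_never_decreases_p_fold(self, tet_classes, sn_lib):
        # duplicated arrangement vs the same chain with fresh unique pairs
        perm = circular_permutations(tet_classes[0])[5]
        par = sorted({m.edge for m in perm.slots if m.orientation == PARALLEL})
        anti = sorted({m.edge for m in perm.slots if m.orientation == ANTIPARALLEL})
        dup_assignment = {
            par[0]: ("P5SN", "P6SN"), par[1]: ("P5SN", "P6SN"),
            par[2]: ("P3SN", "P4SN"), par[3]: ("P7SN", "P8SN"),
            anti[0]: "APHSN", anti[1]: "APHSN",
        }
        dup = build_arrangement(perm, dup_assignment, sn_lib)
        p_dup = folding_probability(dup, sn_lib).p_fold
        lib_u, uniq_assignment = unique_assignment_for(perm, random.Random(5))
        uniq = build_arrangement(perm, uniq_assignment, lib_u)
        p_uniq = folding_probability(uniq, lib_u).p_fold
        assert p_dup <= p_uniq == 1


class TestDesignSearch:
    def test_multiset_parsing(self):
        spec = parse_module_multiset("P3SN:P4SN x2, APHSN x2, GCNSN")
        assert spec == [(("P3SN", "P4SN"), 2), ("APHSN", 2), ("GCNSN", 1)]

    def test_single_duplication_attains_certain_folding(self, tet_classes, sn_lib):
        report = design_search(
            tet_classes[:1],
            "P3SN:P4SN, P5SN:P6SN x2, P7SN:P8SN, APHSN, BCRSN",
            sn_lib,
        )
        assert report.max_p_fold == 1
        assert report.entries == sorted(
            report.entries, key=lambda e: (-e["p_fold"], e["permutation"], e["assignment"])
        )

    def test_infeasible_geometry_census(self, tet_classes, sn_lib):
        with pytest.raises(InfeasibleDesignError):
            design_search(
                tet_classes[:1],
                "P3SN:P4SN x2, P5SN:P6SN x2, P7SN:P8SN",  # 5 parallel pairs
                sn_lib,
            )

    def test_contracted_structure_of_designed_fold(self, unique_tet):
        arr, lib = unique_tet
        state = FoldingState.from_arrangement(arr, lib)
        for (i, j) in sorted(arr.on_target):
            state = state.form(i, j)
        g = contracted_structure(state)
        used = {n for e in g.edges() for n in e}
        assert len(used) == 4 and g.number_of_edges() == 6
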