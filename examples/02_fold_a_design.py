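"""Score a cage design with the deterministic folding model.

Builds a 12-slot tetrahedron arrangement in which the P5SN:P6SN
heterodimer occupies two different edges, then expands every folding
pathway: at each step the complementary pair with the shortest effective
intra-chain distance forms, ties split the pathway, and sterically
impossible events are pruned.  P_F is the fraction of pathways ending in
the tetrahedron.
"""

from ccpo import (
    FoldingState,
    build_arrangement,
    candidate_moves,
    circular_permutations,
    folding_probability,
    sn_library,
    tetrahedron_topologies,
)
from ccpo.topology import PARALLEL

library = sn_library()
t1 = tetrahedron_topologies()[0]
perm = circular_permutations(t1)[0]

par_edges = sorted({s.edge for s in perm.slots if s.orientation == PARALLEL})
anti_edges = sorted({s.edge for s in perm.slots if s.orientation != PARALLEL})
assignment = {
    par_edges[0]: ("P3SN", "P4SN"),
    par_edges[1]: ("P5SN", "P6SN"),
    par_edges[2]: ("P5SN", "P6SN"),  # second copy of the same pair
    par_edges[3]: ("P7SN", "P8SN"),
    anti_edges[0]: "APHSN",
    anti_edges[1]: "BCRSN",
}
arrangement = build_arrangement(perm, assignment, library)
print("chain:", arrangement.assignment_string())

state = FoldingState.from_arrangement(arrangement, library)
print("\nfirst-step candidates (slot pair -> distance):")
for pair, dist in candidate_moves(state):
    print(f"  {pair}: {dist}")

outcome = folding_probability(arrangement, library)
print(
    f"\nP_F = {outcome.p_fold} "
    f"({outcome.folded_leaves} of {outcome.total_leaves} pathways fold), "
    f"weighted variant {outcome.p_fold_weighted}"
)
# P_F = 1 means every pathway ends in the tetrahedron; a value below 1
# would mean some formation order lets the duplicated copies cross-pair
# into a structure that is not the target cage.
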