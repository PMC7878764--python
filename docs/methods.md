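# Methods

This note records the models implemented in `ccpo`, the conventions and
numerical choices behind them, and what the synthetic-data studies do and
do not demonstrate.

## Chain topologies as double traces

A single-chain polyhedral cage visits every edge of its target graph
exactly twice — once per peptide of the CC dimer occupying that edge — so
chain topologies are closed **double traces** of the graph. Two conditions
restrict the walks to physically realizable chains:

* **Properness.** No step is immediately followed by the same edge
  reversed. An immediate retrace would put the two peptides of one dimer
  on adjacent slots joined by a pentapeptide linker at a vertex with no
  room for a turn of zero length around a rigid segment.
* **Strongness (single-corner condition).** At every vertex, build the
  multigraph whose nodes are the incident edges and whose links are the
  walk's (in-edge → out-edge) transitions through that vertex; the walk is
  strong when this multigraph is connected (each incident edge contributes
  exactly two link endpoints, so connectedness means the transitions form
  one cycle — one corner per vertex). A disconnected transition multigraph
  would split the vertex into two independent crossings that nothing holds
  together.

Enumeration is exhaustive backtracking over directed-edge extensions,
anchored so that the first step traverses the lexicographically first edge
(both directions are used as anchors); every cyclic walk therefore appears
in at least one rotation. Classes are formed under cyclic rotation, walk
reversal and graph automorphism (automorphisms via networkx VF2), with the
lexicographically minimal vertex-sequence encoding as the canonical key.
On the tetrahedron this yields exactly **3 classes** (T1: 4 parallel / 2
antiparallel edges; T2, T3: 3/3); an independent unanchored enumeration
with post-hoc filtering reproduces the class sets on small graphs. Labels
T1.1 … T1.12 number start positions along the canonical walk; they are a
package convention and need not match numbering used elsewhere (e.g. a
published "1.10" label from supplementary material).

Parity: in a closed walk, each vertex is entered as often as it is left,
which forces every vertex of a 3-regular graph to carry an odd number of
incident antiparallel edges — hence no tetrahedron class can have fewer
than 2 antiparallel edges.

## Effective intra-chain distance

The chain is modelled as a weighted junction graph: each slot contributes
N- and C-terminus nodes joined by a weight-1 link (crossing one module),
consecutive slots are joined by weight-0 linker links, and each formed
pair adds weight-0 identification links between the termini its rigid
dimer geometry superimposes (parallel: N–N and C–C; antiparallel: N–C and
C–N). The distance of a candidate pair is the minimum over its two
terminus pairings (N–N vs C–C for parallel, N–C vs C–N for antiparallel)
of shortest-path length. Consequences worth noting:

* unfolded chain: parallel candidates at slot gap *g* have distance *g*,
  antiparallel candidates *g* − 1 (adjacent antiparallel hairpins: 0);
* a formed pair is one segment: crossing it end-to-end costs 1;
* a candidate spanning a formed antiparallel hairpin passes the hairpin's
  turn end at zero cost (its outer termini are identified), so such a
  hairpin removes **two** crossings from spanning paths, not one;
* distances are non-increasing along any pathway, because formation only
  ever adds zero-weight links. This monotonicity is asserted at run time
  when auditing is enabled.

Internally distances are computed by contracting the zero-weight
components (union–find) and running breadth-first search on the resulting
unit-cost multigraph; the public `effective_graph` exposes the full
weighted graph, and tests verify both routes against exhaustive
simple-path enumeration.

Chain termini are ordinary nodes. Simulated trajectories suggest terminal
segments fold slightly faster than their distance alone predicts; the
model deliberately omits any terminal correction.

## Steric filter

Peptide segments are rigid bodies. The default (`strict`) rule prohibits
a formation event when, after adding the candidate's identification
links, any segment's N and C termini would be joined by a zero-weight
path — the segment would have to begin and end at the same spatial point.
This single criterion subsumes the two special cases one can state
directly: parallel candidates on chain-adjacent slots are impossible (the
linker cannot span the dimer length), and an antiparallel candidate at
slot gap 2 is impossible because it would trap the intervening module in
a zero-length loop. Antiparallel hairpins of adjacent slots remain
allowed (the linker turns at the dimer end). Two weaker modes exist for
comparison: `candidate-only` (test only the candidate's own opposite-end
termini before formation) and `adjacency-only` (prohibit nothing but
adjacent parallel pairs). The strict rule is the default because it is
the only one of the three under which duplicated-module cages reproduce
the designed folding behaviour; the full prohibition set used in earlier
work is not restated in public sources, so divergences are possible and
the mode switch keeps them inspectable.

## Folding model and P_F

From the unfolded state, at every step each complementary free slot pair
(on- and off-target, all copy combinations) is a candidate; sterically
prohibited events are removed; all candidates attaining the minimum
distance form, one per branch (ties split the pathway, they never
co-fire). Distances are recalculated in every child. A state with no
admissible event is terminal: **folded** if all slots are paired and the
contraction — each formed pair an edge, zero-weight junctions merged into
vertices — is a simple graph isomorphic to the target polyhedron
(checked with networkx VF2), otherwise **misfolded** (wrong matchings and
stuck states alike). An `on-target` switch restricts "folded" to the
designed matching; for the built-in studies both verdicts coincide.

`P_F` is the fraction of root-to-leaf pathways ending folded, in exact
`Fraction` arithmetic. Because the model is Markovian in the set of
formed pairs, the leaf census is computed by memoized recursion over
states (a node cap, default 10⁶ distinct states, guards pathological
inputs). Since the census counts ordered pathways and the splits are not
weighted, a secondary statistic — uniform weight 1/branching at every
split — is reported alongside; the two agree at the extremes that matter
(`P_F` = 1 or 0) and neither replaces the other.

`design_search` enumerates permutations × multiset placements ×
heterodimer chain orders. Arrangements with identical complementarity
structure (which slots can pair, with what geometry) provably share a
pathway tree, so each unique structure is evaluated once; the full
enumeration is still reported row by row.

Model behaviour at the design points used in the tests: with six unique
cognate pairs every pathway folds (`P_F` = 1 for all 3 topologies × 12
permutations × random assignments); with one or two duplicated
heterodimer pairs the exhaustive search attains maximum `P_F` = 1; with
three distinct types (two heterodimer pairs + the antiparallel homodimer,
each on two edges) the maximum is still 1; with one pair used on three
edges the maximum over topology T1 falls below 1 (37/40 at best).

## Fitting models

All fits are nonlinear least squares (lmfit/`leastsq`), pure functions of
(data, initialization, tolerances). Temperatures are kelvin internally
and °C at interfaces; energies kJ/mol; R = 8.314462618 J mol⁻¹ K⁻¹.
Folding enthalpies are negative; ΔG_fold is positive for a protein folded
without denaturant and crosses zero at [G] = ΔG_fold/m.

* **Kinetics** `y = a·exp(−kt) + bt + c`. Initialization: background and
  drift from a linear fit to the final quarter, amplitude from the
  drift-corrected initial value, rate from a log-linear regression of the
  drift-corrected early phase. A post-fit warning flags spans shorter
  than ~1/k.
* **Chemical denaturation** `FRET = B + C(1 + D[G])·s([G])` with
  `s = [1 + exp(−(ΔG_fold − m[G])/RT)]⁻¹`; the sloped folded baseline is
  carried by D. Midpoint initialized from the normalized half-crossing.
* **Thermal melts.** Two-state: `α_f = K/(1+K)`,
  `K = exp(−ΔH(1 − T/T_m)/RT)` (so α_f(T_m) = ½ exactly), signal
  `MRE_u(T) + α_f·(MRE_f(T) − MRE_u(T))` with linear baselines fitted
  jointly — the baseline form is unstated in the source protocols, and
  linear-in-T is the field standard. Three-state U ⇌ I ⇌ F with
  K_i = [I]/[U], K_f = [F]/[I] of the same van 't Hoff form (midpoints
  T_m,1, T_m,2) and the intermediate carrying half the folded CD signal:
  observed fraction α_f + ½α_i. Populations are evaluated as a softmax
  over log-Boltzmann weights so extreme enthalpies stay finite. In the
  saturated limit K_i → ∞ across the window, α_f collapses exactly onto
  the two-state curve with (ΔH_f, T_m,2) — verified to 10⁻¹² and used as
  a consistency check. A joint 8-parameter fit outperformed the two-stage
  estimate-baselines-then-fit procedure in recovery studies (baseline
  extrapolation error biases the normalized signal) and is the default.
* **Formation order.** First passage of the native-contact fraction
  through the threshold (default 0.5); trajectory traces recross, so a
  sustained-crossing variant (threshold held for a window of samples) is
  provided as the conservative cross-check. Ties are reported as ties and
  never-crossing CCs as unformed.

## Synthetic data and what the studies show

Generators add seeded Gaussian noise with standard deviation expressed as
a fraction of the clean signal range; measured curves are averages of
three independent replicates, mirroring the usual measurement protocols
(stopped-flow traces averaged over n ≥ 3 shots, CD melts over three
technical replicates). The reference study conditions
(`biophys.REFERENCE_CONDITIONS`) are: k = 24 s⁻¹ sampled every 1 ms for
0.5 s; ΔG_fold = 25 kJ/mol, m = 10 kJ/mol/M (midpoint 2.5 M) over 0–5 M
in 0.1 M steps; melts over 0–90 °C in 1 °C steps with T_m = 56 °C,
ΔH = −250 kJ/mol (two-state) and T_m,1/T_m,2 = 57.5/44 °C,
ΔH_i = ΔH_f = −300 kJ/mol (three-state); noise fraction 5 %.

Recovery at these conditions (medians over the seeded ensembles): k to
~1 %, ΔG_fold and m to ~4 %, two-state ΔH to ~5 % and all melting
midpoints to ≲ 0.2 %. The three-state enthalpies are different: a single
melt sampled at 1 °C with triplicate averaging determines ΔH_i and ΔH_f
only to ~9–11 % median error, **even when the fit is initialized at the
true parameters** — the limit is the information content of the curve
(strong ΔH–baseline and ΔH_i–ΔH_f correlations), not the optimizer, and
it persists across the realistic (ΔH, midpoint-separation) range. Users
should treat single-melt three-state enthalpies as order-of-magnitude
estimates; midpoints are reliable.

The generators emulate curve shapes, noise and replicate averaging only.
They do not model instrument dead time beyond metadata, baseline
curvature, temperature-dependent noise, aggregation during melts, or
photobleaching drifts beyond the linear term — so passing recovery tests
demonstrates estimator correctness and identifiability under the stated
conditions, not robustness to every artefact of real measurements.

## Degenerate inputs and tie-breaking

Candidate ordering (and hence tree/report ordering) is canonical by slot
index; class labels by canonical walk encoding; identical inputs yield
byte-identical reports (timestamps are never embedded). Empty libraries
load (schema tests only); empty linkers are permitted with a warning;
single-edge graphs have no proper trace (the only closed double walk
retraces immediately) but do have the improper antiparallel hairpin.
Graphs must be connected and simple — multi-edges and self-loops are
rejected as no cage in scope needs them.

## Known limitations

* The folding model is purely topological: module stabilities, rates and
  sequences never influence pathway order (by design — arrangement
  outcome depends only on chain placement), so kinetic competition
  between tied branches is not modelled.
* Inter-chain misassembly (domain swapping between molecules,
  aggregation) is out of scope; the model only discovers intramolecular
  misfolds.
* The steric rule is a graph-level surrogate for excluded volume; it
  cannot see clashes that require 3-D coordinates.
* `P_F` weights pathways, not time: it is a census of the deterministic
  tree, not a kinetic rate prediction.
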