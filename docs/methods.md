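# Methods

This note records the models, parameter choices and numerical conventions
behind cliquefold, the assumptions they rest on, and what the synthetic
test bed does and does not demonstrate.

## Graph formulation

A problem instance is a set of strands, candidate secondary structures per
strand, and candidate interaction sites per strand pair. Candidates are
vertices; an edge joins two vertices iff they are compatible. The
compatibility rule is deliberately permissive: only two kinds of conflict
exist — (i) two structures of the same strand, and (ii) a nucleotide
position paired in both vertices. Interleaved-but-disjoint pair sets remain
compatible, which is what lets predicted complexes contain pseudoknots and
crossing interactions without any special-casing.

Two conventions sharpen corner cases the formulation leaves open:

* **Shared identical pair.** Two candidates that pair the same position —
  even to the same partner — are incompatible. A same-partner overlap only
  arises from redundant inputs, and treating it as a conflict prevents the
  pair's energy from being counted twice.
* **Duplicates.** Candidates with identical strand scope and pair set are
  collapsed to the first occurrence at graph build time; merged candidate
  sources routinely emit identical structures.

Every strand receives one empty structure vertex (no pairs, energy 0) if
none was supplied. This guarantees the one-structure-per-strand constraint
is always satisfiable, and it is why clique repair (below) can never fail.

Coordinates are 0-based internally; every file format is 1-based. An
interaction site must be internally non-crossing (pairs sorted by position
on one strand must descend on the other — the antiparallel duplex
geometry); crossing interactions are expressed *between* sites, never
within one.

## Energy models

Candidates arrive from heterogeneous sources, so all are re-scored on a
common scale (kcal/mol at 37 °C, Turner 2004 parameters, embedded as a
plain-text resource in `cliquefold/energy/data/`):

* **Pseudoknot-free structures** — nearest-neighbor loop decomposition:
  stacks, hairpins (length term, terminal mismatch, special tri/tetra/hexa
  loops, AU/GU closing penalty for triloops), bulges (size 1 keeps the
  flanking stack; larger sizes pay helix-end penalties), internal loops
  (length term, Ninio asymmetry capped at 3.0 kcal/mol, terminal
  mismatches), multiloops (affine: 9.3 closing + −0.9 per branch + 0 per
  unpaired nucleotide, plus AU/GU end penalties), exterior loop (AU/GU end
  penalties only). Loop-length tables run to 30 with the standard
  1.07856·ln(n/30) logarithmic extrapolation.
* **Interaction sites** — the same machinery applied as a duplex: 4.10
  initiation, stacks and bulge/internal-loop terms between consecutive
  pairs, AU/GU penalties at both duplex ends.
* **Pseudoknotted structures** — the loop decomposition is undefined, so
  the energy is the plain sum of stacking energies over stacked adjacencies
  ((i,j) on (i+1,j−1), or the adjacent-on-both-strands analogue); isolated
  pairs contribute 0.

Omissions, chosen for a minimal well-defined model: no dangling ends, no
coaxial stacking, no special 1×1/2×2/1×n/2×3 internal-loop tables (the
generic internal-loop formula covers them), no all-C hairpin penalty, no
partition functions or temperature dependence. Tests compare against an
independent reference evaluator (`RNAeval -d0`) with a 0.5 kcal/mol
tolerance on fixtures that avoid the special loop tables; on plain
stems, hairpins, bulges and simple multiloops the two agree exactly.

Only canonical pairs (A-U, G-C, G-U) are scorable; a non-canonical pair in
any candidate is a hard scoring error naming the pair. Lonely (isolated)
pairs are allowed.

**Weights.** The solver maximizes total weight with
w(v) = max(0, −ΔG(v)). The clamp keeps the maximization well-posed:
a destabilizing candidate (ΔG > 0) gets weight 0 and can never be
preferred over the empty structure on weight grounds, while final *ranking*
uses the true summed energies, so such candidates still sort behind.

## The search

The constrained MWCP is solved by a breakout local search specialised to
the constraint structure. Move sets (all maintained over a bitset
adjacency representation, with a definition-level reference implementation
used as an oracle in tests):

* PA — interaction vertices outside C adjacent to all of C (addable);
* OM — same-kind replacement pairs (v, u), v outside C blocked only by
  u ∈ C: interaction-for-interaction or structure-for-structure, which
  preserves one-structure-per-strand by construction;
* OC — interaction vertices outside C (restart candidates).

Structure vertices only ever change via replacement; interaction vertices
via add/remove/replace. Any move that would produce a weak clique (zero
base pairs) is never offered.

One iteration = one steepest descent to a local optimum (best
strictly-improving add/replace, ties broken uniformly with the run's
seeded RNG) followed by one perturbation. Perturbation is directed with
probability P0: L = ⌈0.1·|V|⌉ moves, each the least-degrading legal
non-tabu move, accepting a degrading replace only while the new/old weight
ratio stays ≥ αs and a remove only while the removed weight is ≤ (1−αr) of
the clique weight; with probability 1−P0 the L moves are uniform over
legal non-tabu moves. After more than T consecutive non-improving descents
— or when no legal weak move exists — a strong perturbation runs instead:
force a random outside interaction into C, keep each strand's structure if
still compatible else replace it with a random compatible one (the empty
structure as guaranteed fallback), then drop interactions that no longer
fit. Vertices leaving C are tabu for φ moves; the non-improvement counter
resets after a restart.

Defaults: 500 iterations (user-settable), 5 restarts, T = 10,
αs = αr = 0.5, φ = 7, P0 = 1, L0 = Lmax = 0.1·|V| (so the perturbation
strength is constant; it is rounded up with a minimum of 1 because L is a
move count). Iteration granularity — descent + perturbation = one of the
500 — follows the two-phase alternation of breakout local search.

Every distinct valid clique encountered in either phase is archived
(keyed by member set), so sub-optimal complexes come for free. The
initial clique is a random interaction vertex plus one compatible
structure per strand; a graph with *no* interaction candidates is refused
with a diagnostic rather than degenerating into single-strand folding,
since the object of the tool is complexes. All randomness flows from one
seeded generator: identical input + seed gives an identical archive.

## Post-processing and evaluation

Strands with character-identical sequences make complex labelings
arbitrary. Complexes are canonicalized by brute force over all
permutations within each identical-sequence class (lexicographically
minimal pair-set serialization wins), capped at class size 6 with an
identity-permutation fallback and a logged warning — exact for realistic
strand multiplicities, and factorial blowup is impossible below the cap.
One representative per canonical form survives (lowest energy, first
encountered on ties); the list is sorted by energy, ties broken by
canonical key for cross-platform determinism, and truncated to
`max_solutions` (default 10).

Evaluation counts base pairs: TP/FP/FN from set operations, TN from a
universe of all N(N−1)/2 unordered position pairs over the whole complex
(the most inclusive convention; the alternative — canonically pairable
positions only — would shrink TN and move MCC, which is worth remembering
when comparing absolute MCC values across toolchains). Zero-denominator
statistics return 0 so means over many complexes stay defined. Before
counting, the predicted set is mapped through the within-class relabeling
that maximizes agreement with the reference, so symmetry is never
penalized. The best-over-top-k summary (default k = 10) and means over
repeated seeded executions (default 5) mirror how stochastic multi-output
predictors are normally benchmarked.

## Synthetic test bed

The generator emulates what merged external prediction tools would supply:
random strands (default 3 strands of 20–40 nt) with per-strand structure
candidates (default 4; helices of 2–5 pairs, a 0.25 chance of a crossing
second helix making the candidate pseudoknotted) and per-pair interaction
candidates (default 2). Complementarity is enforced by sequence fill-in
(pair letters drawn GC-biased, locked positions respected), so every
generated candidate is canonically pairable and the energy layer is always
exercised. An overlap knob (default 0.3) makes candidates deliberately
reuse positions, shaping conflict density in the compatibility graph.

With `plant_optimum`, a known optimum is constructed: a GC hairpin per
strand and GC duplexes between consecutive strands, sized to the positions
still free on each strand, with every decoy interaction forced to overlap
a planted position (decoy structures conflict with the planted one by the
same-strand rule). The exhaustive oracle then verifies the plant is the
strictly dominant optimum; if a draw fails verification the instance is
re-drawn from a seed-derived sequence, so the planted property holds by
construction and generation stays deterministic per seed.

The oracle enumerates all structure selections × interaction subsets with
pruning, refusing beyond 2·10⁶ combinations rather than truncating — an
oracle that might be wrong is worse than none.

What passing on this test bed shows: the search, constraint handling,
symmetry removal, energetics plumbing and rankings are correct on graphs
of realistic shape. What it does not show: accuracy on real complexes,
which depends on the quality and diversity of the external candidate
structures and on how well summed per-candidate energies approximate true
complex energies (no inter-candidate loop terms are added when combining).

## Numerical conventions

Weight comparisons use an absolute tolerance of 1e-9 (energies are sums of
two-decimal table entries, so distinct values differ by ≥ 0.01 minus
accumulated float error). Archive identity is exact member-set equality;
equal-weight distinct cliques are kept as distinct solutions. Degenerate
inputs: empty structure scores exactly 0; an empty interaction site is a
type-level error; a single-strand instance (no possible interaction) is
refused by the solver.

## Known limitations

* Complex energy is the sum of member energies: no duplex-junction,
  kissing-loop or inter-candidate loop corrections.
* The nearest-neighbor subset omits dangles/coaxial stacking; absolute
  energies can differ from full-featured evaluators by a few tenths of a
  kcal/mol on structures rich in special loops.
* The search is a heuristic: optimality is verified only at oracle scale
  (tens of vertices); large candidate sets rely on the usual local-search
  evidence.
* Candidates are opaque inputs: cliquefold does not fold or align
  sequences itself, and garbage candidates yield garbage complexes.
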