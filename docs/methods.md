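# Methods

## Model

An instance is a weighted set of adjacencies over a marker set: rows of a
binary matrix of degree 2, identified with a simple graph G whose vertices
are the markers and whose edges are the rows (`linchrom.core`).  A
*multiplicity map* m assigns each marker its maximum copy number (default 1).
A genome is a collection of chromosomes, each a marker sequence flagged
linear or circular; it *realizes* a row subset when every selected adjacency
appears as a consecutive pair (including the wrap-around pair of a circular
chromosome) exactly once over all chromosomes, and every marker occurs
between 1 and m(c) times in total.

The central structural fact is the equivalence between realizable row
subsets and *2m-matchings*: spanning subgraphs with deg(v) ≤ 2m(v) for all
v.  One direction is counting — each of the ≤ m(v) occurrences of v has at
most two neighbours.  The converse is constructive and is exactly what
`decompose_to_chromosomes` implements (below).  Optimization therefore
reduces to a maximum-weight degree-constrained subgraph problem.

Markers are unsigned opaque labels.  Signed markers, gene extremities and
telomere modelling are out of scope; callers using an extremity encoding own
that translation.

## Optimization: gadget reduction to maximum-weight matching

`build_gadget` constructs the auxiliary graph G′ with f(x) = 2·m(x)
interchangeable copy vertices per marker and two port vertices per edge; all
five-or-more gadget edges of an adjacency carry its original weight.  Sizes
are |V(G′)| = Σ_x f(x) + 2|E| and |E(G′)| = Σ_{e={x,y}} (f(x) + f(y) + 1).
A maximum-weight matching of G′ (networkx blossom algorithm; maximum weight,
not maximum cardinality) is translated back by the rule: an adjacency is
selected iff **both** of its ports are matched to copy vertices.  A selected
adjacency contributes 2w(e); a discarded one contributes w(e) through the
{e_x, e_y} edge (or an equivalent single port-copy edge), which yields the
invariant

    weight(matching) = W + weight(selected),  W = total input weight.

This identity is recomputed after every solve (`verify_weight_relation`) and
a failure raises `ReductionInvariantError`: it is the contract that guards
both the gadget construction and the third-party matching solver.

Maximum-weight matching decomposes over connected components, so the solver
runs per component of G; this changes nothing mathematically and keeps the
per-call problem small.  Weights are `fractions.Fraction` throughout and are
scaled to a common integer denominator before the blossom call, so the
optimum weight is exact — tests compare optima with `==`, not with a
tolerance.  Floats are accepted at the API boundary and converted to their
exact binary value.

## Construction: Eulerian decomposition

Within each connected component of the selected subgraph:

* all degrees even → one Eulerian circuit → one circular chromosome;
* 2k odd-degree vertices → odd vertices are paired lexicographically and
  joined by virtual edges, a circuit of the augmented multigraph is cut at
  the virtual edges → k edge-disjoint open trails → k linear chromosomes;
* an isolated marker → a length-1 linear chromosome, so every marker occurs
  at least once.

This produces the minimum number of chromosomes for the component (1 closed
trail, or k open trails for 2k odd vertices).  Any valid trail collection
would do; minimizing chromosome count is this package's choice, on the view
that a reconstruction should not fragment a component without evidence.
Similarly, each marker occurs the minimum feasible number of times,
(deg(v) + #trail-ends at v)/2 ≤ m(v), rather than being padded to exactly
m(v) with silent extra copies: the upper bound m is a budget, not a target,
and padded copies carry no signal.  Circular chromosomes of length 1 or 2
cannot arise (the graph is simple with no duplicate rows); this is asserted.

Ties among equally optimal row subsets are resolved by whatever the matching
solver returns, post-processed deterministically (lexicographic vertex
orderings everywhere an arbitrary choice exists), so repeated runs on one
input give byte-identical output.  Tests compare optimum weights, never
specific row sets, except where a planted instance guarantees uniqueness.

## Brute-force oracles (`linchrom.oracle`)

Ground truth at toy scale, kept independent of the pipeline they check:

* `brute_force_max_2m_matching` enumerates all 2^rows subsets (≤ 20 rows)
  with vectorized degree checks and exact integer-scaled weights.
* `solve_23ucr_brute` decides whether a 2,3-uniform hypergraph admits a
  *graph covering* (one vertex pair per 2-edge, two per 3-edge; the union
  taken as a set) that is a disjoint union of cycles and paths —
  operationalized as maximum degree ≤ 2 — after removing at most k
  hyperedges.  Removal subsets and the 3^(#3-edges) covering choices are
  enumerated lexicographically; witnesses are returned.
* `brute_force_row_removal` decides the same question on the matrix side by
  direct search: with unit multiplicities every marker occurs exactly once,
  so candidate genomes are precisely the cycle decompositions of
  permutations of the marker set; for each arrangement the rows it fails to
  realize must be removed.  This deliberately does **not** delegate to the
  hypergraph solver, so the agreement test between the two routes is a real
  two-sided check of the matrix/hypergraph correspondence rather than a
  tautology.

The NP-completeness reductions themselves (the SAT-variant gadgetry behind
the degree-3 hardness) are not implemented: their gadget hyperedge sets are
not specifiable from the available description, and they contribute proof
machinery, not computation.

## Synthetic data (`linchrom.synth`)

`generate_planted` emulates the downstream half of an ancestral
reconstruction experiment: a hidden ancestral genome (random chromosomes,
optionally circular, optionally with duplicated markers of m = 2) emits its
true adjacency set as heavy rows, and spurious candidate adjacencies are
added as lighter noise rows.  In *strict mode* noise rows connect only
markers already saturated in the planted genome (degree = 2m) and every
noise weight lies strictly below every true weight; an exchange argument
then makes the planted row set the unique optimum, so recovery tests can
compare row sets exactly.  Requests that cannot be honoured (circular
chromosomes needing ≥ 3 marker copies, a noise pool smaller than requested)
are rejected with the achievable count rather than silently under-delivered.
Weights are rationals with denominator 10^4, keeping all arithmetic exact.
Defaults: 8 markers, one chromosome, circular with probability 0.5, no
duplication, true weights in (1, 2], noise in (0, 0.5].

What the generator does *not* emulate: phylogenetic weight estimation,
missing true adjacencies, correlated noise, or marker families beyond copy
number 2.  Passing recovery tests therefore shows the optimizer finds the
planted optimum under weight separation — not that real conservation-derived
weights identify the true ancestral genome.

`generate_blocked` assembles many planted instances under disjoint marker
namespaces into one large input whose graph splits into moderate connected
components, the shape real multi-replicon datasets take; it drives the
scalability sweep (125 linkage groups of 80 markers / 120 rows = 10,000
markers, 15,000 rows; measured runtime grows roughly linearly in the number
of groups, exponent ≈ 1.1 on a 5× sweep).

## File formats and CLI

Tab-separated UTF-8 text throughout: adjacency TSV (`a b w`, with an opt-in
4-column degree-3 dialect for oracle inputs), multiplicity TSV, and a
one-chromosome-per-line genome format (`C …` circular, `L …` linear) in
which circular sequences are canonicalized by rotation and reflection to the
lexicographic minimum, so write/read round-trips are stable.  Readers reject
malformed input with line numbers; writers emit files their readers accept.
A bespoke genome format is used instead of GRIMM-style dialects because
markers here are unsigned and may repeat; exporting to signed formats would
imply orientation semantics the model does not carry.  Exit codes: 0
success, 2 validation error, 3 internal invariant failure.

## Known limitations

* The blossom solver is pure Python; very large single connected components
  (tens of thousands of gadget vertices) are slow even though the algorithm
  is polynomial.  The asymptotic exponent of the underlying matching routine
  is inherited from networkx, and no claim is made about matching the best
  theoretical bound.
* Degree-3 rows (three-marker intervals) are handled only by exponential
  oracles — the problem is NP-complete there, and no heuristic is provided.
* Multiplicities enter only as upper bounds; there is no penalty or prior on
  using fewer copies.
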