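"""Ground-truth brute-force solvers and structural checkers.

Everything here is exponential-time and restricted to toy sizes; the point is
independence from the polynomial pipeline, so these functions enumerate
candidate solutions directly from the definitions.  The module also covers
the objects that mark the tractability boundary: 2,3-uniform hypergraphs,
their graph coverings by disjoint cycles and paths, and row removal on
degree-2/3 matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np

from linchrom.core import (
    AdjacencyMatrix,
    Genome,
    MultiplicityMap,
    Row,
    SelectedSubgraph,
)

MAX_BRUTE_ROWS = 20
MAX_COVER_EDGES = 10


@dataclass
class Hypergraph23:
    """A 2,3-uniform hypergraph: every hyperedge has exactly 2 or 3 vertices."""

    vertices: frozenset[str]
    edges2: frozenset[frozenset[str]]
    edges3: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        self.vertices = frozenset(self.vertices)
        self.edges2 = frozenset(frozenset(e) for e in self.edges2)
        self.edges3 = frozenset(frozenset(e) for e in self.edges3)
        for e in self.edges2:
            if len(e) != 2:
                raise ValueError(f"2-edge {sorted(e)} does not have 2 vertices")
        for e in self.edges3:
            if len(e) != 3:
                raise ValueError(f"3-edge {sorted(e)} does not have 3 vertices")
        for e in self.edges2 | self.edges3:
            if not e <= self.vertices:
                raise ValueError(f"hyperedge {sorted(e)} uses undeclared vertices")

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return self.edges2 | self.edges3


@dataclass
class Covering:
    """A graph covering: one vertex pair per 2-edge, two pairs per 3-edge.

    ``edge_union`` is the union of all chosen pairs; the covering is *valid*
    (disjoint cycles and paths) iff that simple graph has maximum degree <= 2.
    """

    choices: dict[frozenset[str], frozenset[frozenset[str]]] = field(default_factory=dict)

    @property
    def edge_union(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for pairs in self.choices.values():
            out |= pairs
        return out

    def max_degree(self) -> int:
        deg: dict[str, int] = {}
        for pair in self.edge_union:
            for v in pair:
                deg[v] = deg.get(v, 0) + 1
        return max(deg.values(), default=0)


def is_2m_matching(selected: SelectedSubgraph, mult: MultiplicityMap) -> bool:
    """deg(v) <= 2m(v) for every marker: the exact condition for a degree-2
    row subset to be realizable by a multichromosomal (circular/linear) genome."""
    g = selected.graph()
    return all(g.degree(v) <= mult.f(v) for v in g.nodes)


def is_c1p_degree2(selected: SelectedSubgraph) -> bool:
    """Degree-2 consecutive-ones check: graph is a disjoint union of paths."""
    g = selected.graph()
    if any(d > 2 for _, d in g.degree):
        return False
    return all(
        nx.is_tree(g.subgraph(c)) for c in nx.connected_components(g)
    )


def is_ci1p_degree2(selected: SelectedSubgraph) -> bool:
    """Degree-2 circular-ones check: graph is one cycle, or disjoint paths.

    The cycle case requires the cycle to span every vertex: an extra isolated
    marker would have to sit somewhere on the circular column order and would
    break one of the cycle adjacencies.
    """
    g = selected.graph()
    if any(d > 2 for _, d in g.degree):
        return False
    comps = list(nx.connected_components(g))
    cyclic = [c for c in comps if g.subgraph(c).number_of_edges() == len(c)]
    if not cyclic:
        return True  # disjoint paths (isolated vertices are trivial paths)
    return len(cyclic) == 1 and len(cyclic[0]) == g.number_of_nodes()


def check_genome_realizes(
    genome: Genome, selected: SelectedSubgraph, mult: MultiplicityMap
) -> bool:
    """Does the genome realize the selected rows?

    True iff every selected row's marker pair is consecutive (including the
    wrap-around pair of circular chromosomes) exactly once across all
    chromosomes, and every marker of the parent matrix occurs between 1 and
    m(marker) times in total.
    """
    adj = genome.adjacency_multiset()
    for r in selected.rows:
        if adj.get(r.pair(), 0) != 1:
            return False
    counts = genome.occurrence_counts()
    for v in selected.parent.markers:
        if not 1 <= counts.get(v, 0) <= mult[v]:
            return False
    return True


def brute_force_max_2m_matching(
    matrix: AdjacencyMatrix, mult: MultiplicityMap
) -> tuple[Fraction, frozenset[str]]:
    """Exact maximum-weight 2m-matching by enumerating all row subsets.

    Subsets are enumerated as bit masks with vectorized degree checks; weights
    are compared exactly on a common integer denominator.  Rejects instances
    with more than 20 rows.
    """
    rows = matrix.rows
    if len(rows) > MAX_BRUTE_ROWS:
        raise ValueError(f"instance too large for brute force: {len(rows)} rows")
    if not rows:
        return Fraction(0), frozenset()
    markers = sorted(matrix.markers)
    midx = {m: i for i, m in enumerate(markers)}
    incidence = np.zeros((len(markers), len(rows)), dtype=np.int64)
    for j, r in enumerate(rows):
        for c in r.columns:
            incidence[midx[c], j] = 1
    caps = np.array([mult.f(m) for m in markers], dtype=np.int64)

    n = len(rows)
    masks = np.arange(1 << n, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(np.int64)  # (2^n, n)
    degrees = bits @ incidence.T  # (2^n, n_markers)
    feasible = np.all(degrees <= caps, axis=1)

    scale = 1
    for r in rows:
        d = r.weight.denominator
        scale = scale * d // np.gcd(scale, d)
    wints = np.array([int(r.weight * scale) for r in rows], dtype=object)
    totals = bits @ wints  # object dtype keeps exact big-int arithmetic
    totals = np.where(feasible, totals, -1)
    best = int(np.argmax(totals))
    best_ids = frozenset(rows[j].row_id for j in range(n) if (best >> j) & 1)
    weight = sum((rows[j].weight for j in range(n) if (best >> j) & 1), Fraction(0))
    return weight, best_ids


def matrix_to_hypergraph(matrix: AdjacencyMatrix) -> Hypergraph23:
    """Rows of degree 2/3 become 2-/3-edges; the correspondence is one-to-one."""
    e2, e3 = set(), set()
    for r in matrix.rows:
        if r.degree == 2:
            e2.add(r.columns)
        elif r.degree == 3:
            e3.add(r.columns)
        else:
            raise ValueError(f"row {r.row_id} has degree {r.degree}, not 2 or 3")
    return Hypergraph23(
        vertices=frozenset(matrix.markers), edges2=frozenset(e2), edges3=frozenset(e3)
    )


def hypergraph_to_matrix(h: Hypergraph23) -> AdjacencyMatrix:
    """Inverse of :func:`matrix_to_hypergraph`; rows in lexicographic order."""
    rows = [
        Row(f"r{i + 1:06d}", e, Fraction(1))
        for i, e in enumerate(sorted(h.edges, key=lambda e: sorted(e)))
    ]
    return AdjacencyMatrix(markers=sorted(h.vertices), rows=rows)


def _pair_choices(h: frozenset[str]) -> list[frozenset[frozenset[str]]]:
    """Admissible covering choices for one hyperedge: the single pair of a
    2-edge; any 2 of the 3 vertex pairs of a 3-edge (3 choices)."""
    if len(h) == 2:
        return [frozenset({h})]
    pairs = [frozenset(p) for p in itertools.combinations(sorted(h), 2)]
    return [
        frozenset(c) for c in itertools.combinations(pairs, 2)
    ]


def solve_23ucr_brute(
    h: Hypergraph23, k: int
) -> tuple[bool, tuple[frozenset[frozenset[str]], Covering] | None]:
    """Covering by disjoint cycles and paths after removing <= k hyperedges.

    Enumerates removal subsets in lexicographic order by size, and for each
    the full product of covering choices of the kept hyperedges; accepts when
    the union of chosen pairs has maximum degree <= 2.  Returns a witness
    (removed set, covering) for positive instances.
    """
    edges = sorted(h.edges, key=lambda e: sorted(e))
    if len(edges) > MAX_COVER_EDGES:
        raise ValueError(f"instance too large for brute force: {len(edges)} hyperedges")
    for r in range(min(k, len(edges)) + 1):
        for removed in itertools.combinations(edges, r):
            kept = [e for e in edges if e not in removed]
            for combo in itertools.product(*(_pair_choices(e) for e in kept)):
                cov = Covering(choices=dict(zip(kept, combo)))
                if cov.max_degree() <= 2:
                    return True, (frozenset(removed), cov)
    return False, None


def _row_consecutive_in_cycle(columns: frozenset[str], cycle: tuple[str, ...]) -> bool:
    """Are the given columns consecutive somewhere on this cyclic sequence?"""
    n = len(cycle)
    d = len(columns)
    if d > n:
        return False
    if d == n:
        return columns == set(cycle)
    for start in range(n):
        window = {cycle[(start + i) % n] for i in range(d)}
        if window == columns:
            return True
    return False


def _cycle_arrangements(markers: list[str]) -> list[list[tuple[str, ...]]]:
    """All collections of cyclic sequences using each marker exactly once.

    These are precisely the cycle decompositions of permutations of the
    marker set (a length-1 cycle is a marker on its own circular sequence).
    """
    arrangements = []
    for perm in itertools.permutations(range(len(markers))):
        seen = [False] * len(markers)
        cycles = []
        for i in range(len(markers)):
            if seen[i]:
                continue
            cyc = []
            j = i
            while not seen[j]:
                seen[j] = True
                cyc.append(markers[j])
                j = perm[j]
            cycles.append(tuple(cyc))
        arrangements.append(cycles)
    return arrangements


def min_row_removals(matrix: AdjacencyMatrix) -> int:
    """Fewest row removals leaving a matrix realizable by cyclic marker orders.

    Unit multiplicities: each marker occurs exactly once over the cyclic
    sequences, so candidate genomes are enumerated as permutation cycle
    decompositions; for each, the rows it fails to realize must be removed.
    Handles rows of degree 2 and 3; independent of the hypergraph-covering
    route.
    """
    if len(matrix.rows) > MAX_COVER_EDGES:
        raise ValueError(f"instance too large for brute force: {len(matrix.rows)} rows")
    if any(r.degree not in (2, 3) for r in matrix.rows):
        raise ValueError("rows must have degree 2 or 3")
    markers = sorted(matrix.markers)
    best = len(matrix.rows)
    for cycles in _cycle_arrangements(markers):
        missed = sum(
            1
            for r in matrix.rows
            if not any(_row_consecutive_in_cycle(r.columns, c) for c in cycles)
        )
        best = min(best, missed)
        if best == 0:
            break
    return best


def brute_force_row_removal(matrix: AdjacencyMatrix, k: int) -> bool:
    """Can <= k row removals leave a matrix realizable by cyclic marker orders?"""
    return min_row_removals(matrix) <= k
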