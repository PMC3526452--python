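"""Maximum-weight adjacency linearization for degree-2 matrices.

The optimization step finds a maximum-weight *2m-matching* of the adjacency
graph G_M: a spanning subgraph in which every marker v keeps degree at most
2*m(v).  Such subgraphs are exactly the row subsets realizable by a genome of
linear and circular chromosomes, so the optimum solves the weighted
linearization problem for adjacencies.

The 2m-matching is computed by a gadget reduction to ordinary maximum-weight
matching (a weighted Tutte-style construction).  For every marker x we create
f(x) = 2*m(x) interchangeable *copy* vertices; for every adjacency e = {x, y}
two *port* vertices e_x, e_y joined to each other and to all copies of their
endpoint, every gadget edge inheriting weight w(e).  A maximum-weight matching
of the gadget then satisfies

    weight(matching) = W + weight(best 2m-matching),   W = total input weight,

because a selected adjacency contributes 2*w(e) (both ports matched to
copies) while a discarded one still contributes w(e) via the {e_x, e_y} edge.
The identity is verified after every solve; a failure indicates a bug in the
gadget or the matching solver and aborts the run.

The construction step turns the selected subgraph into chromosomes by
Eulerian decomposition: a connected component with all degrees even is one
circular chromosome; a component with 2k odd-degree vertices splits into k
edge-disjoint open trails, i.e. k linear chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable

import networkx as nx

from linchrom.core import (
    AdjacencyMatrix,
    Chromosome,
    Genome,
    MultiplicityMap,
    SelectedSubgraph,
    matrix_to_graph,
    validate_instance,
)

# Gadget vertex labels: ("c", marker, i) is copy vertex number i of a marker,
# ("p", row_id, marker) is the port of edge row_id at that endpoint.
GadgetVertex = tuple[str, str, Hashable]


class ReductionInvariantError(AssertionError):
    """The matching/gadget weight identity failed; solver or gadget is broken."""


@dataclass
class GadgetGraph:
    """Auxiliary graph G' of the f-matching -> matching reduction.

    ``graph`` holds copy and port vertices; ``ports`` maps each original row id
    to its two port vertices (in lexicographic endpoint order).
    """

    graph: nx.Graph
    ports: dict[str, tuple[GadgetVertex, GadgetVertex]]
    f: dict[str, int]

    @property
    def n_copy_vertices(self) -> int:
        return sum(1 for v in self.graph.nodes if v[0] == "c")


@dataclass
class Matching:
    """A set of vertex-disjoint gadget edges with its total weight."""

    edges: frozenset[frozenset[GadgetVertex]]
    weight: Fraction

    def partner(self) -> dict[GadgetVertex, GadgetVertex]:
        out: dict[GadgetVertex, GadgetVertex] = {}
        for e in self.edges:
            u, v = tuple(e)
            out[u] = v
            out[v] = u
        return out


@dataclass
class RunStats:
    """Summary of one linearization run."""

    total_weight: Fraction
    optimum_weight: Fraction
    rows_total: int
    rows_kept: int
    rows_discarded: int
    n_linear: int
    n_circular: int
    occurrence_histogram: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_weight": float(self.total_weight),
            "optimum_weight": float(self.optimum_weight),
            "rows_total": self.rows_total,
            "rows_kept": self.rows_kept,
            "rows_discarded": self.rows_discarded,
            "chromosomes_linear": self.n_linear,
            "chromosomes_circular": self.n_circular,
            "occurrence_histogram": dict(sorted(self.occurrence_histogram.items())),
        }


def build_gadget(g_m: nx.Graph, mult: MultiplicityMap) -> GadgetGraph:
    """Build the gadget graph G' for maximum-weight f-matching, f = 2m.

    For marker x: copy vertices x_1 .. x_{f(x)}.  For edge e = {x, y}: ports
    e_x, e_y; edges {x_i, e_x} for all i, {e_x, e_y}, {y_j, e_y} for all j,
    all of weight w(e).  Vertex insertion is lexicographic so downstream
    traversals are deterministic.
    """
    gp = nx.Graph()
    f = {x: mult.f(x) for x in g_m.nodes}
    for x in sorted(g_m.nodes):
        for i in range(1, f[x] + 1):
            gp.add_node(("c", x, i))
    ports: dict[str, tuple[GadgetVertex, GadgetVertex]] = {}
    for x, y in sorted((min(u, v), max(u, v)) for u, v in g_m.edges):
        data = g_m[x][y]
        w = data["weight"]
        rid = data["row_id"]
        px: GadgetVertex = ("p", rid, x)
        py: GadgetVertex = ("p", rid, y)
        ports[rid] = (px, py)
        for i in range(1, f[x] + 1):
            gp.add_edge(("c", x, i), px, weight=w)
        gp.add_edge(px, py, weight=w)
        for j in range(1, f[y] + 1):
            gp.add_edge(("c", y, j), py, weight=w)
    return GadgetGraph(graph=gp, ports=ports, f=f)


def _integer_scale(weights: list[Fraction]) -> int:
    """Common denominator turning all weights into integers (exact arithmetic)."""
    scale = 1
    for w in weights:
        scale = scale * w.denominator // math.gcd(scale, w.denominator)
    return scale


def solve_max_weight_matching(gadget: GadgetGraph) -> Matching:
    """Maximum-weight matching of the gadget graph (general graphs, blossom).

    Maximum weight, not maximum cardinality.  Fractional weights are scaled to
    a common integer denominator first so the blossom dual updates stay exact.
    """
    gp = gadget.graph
    weights = [d["weight"] for _, _, d in gp.edges(data=True)]
    if not weights:
        return Matching(edges=frozenset(), weight=Fraction(0))
    scale = _integer_scale(weights)
    solve_graph = nx.Graph()
    solve_graph.add_nodes_from(gp.nodes)
    for u, v, d in gp.edges(data=True):
        solve_graph.add_edge(u, v, weight=int(d["weight"] * scale))
    mate = nx.max_weight_matching(solve_graph, maxcardinality=False, weight="weight")
    edges = frozenset(frozenset((u, v)) for u, v in mate)
    weight = sum((gp[u][v]["weight"] for u, v in mate), Fraction(0))
    return Matching(edges=edges, weight=weight)


def recover_f_matching(
    matching: Matching, gadget: GadgetGraph, matrix: AdjacencyMatrix, mult: MultiplicityMap
) -> SelectedSubgraph:
    """Read the optimal 2m-matching off a maximum-weight gadget matching.

    An original adjacency is selected iff *both* of its port vertices are
    matched to copy vertices; a port matched across {e_x, e_y}, or left
    unmatched, excludes the edge.  The recovered subgraph is checked against
    the degree bounds 2m(v) — a violation can only come from a solver bug.
    """
    partner = matching.partner()
    selected: set[str] = set()
    for rid, (px, py) in gadget.ports.items():
        mx = partner.get(px)
        my = partner.get(py)
        if mx is not None and mx[0] == "c" and my is not None and my[0] == "c":
            selected.add(rid)
    sub = SelectedSubgraph(parent=matrix, selected_row_ids=frozenset(selected))
    degrees: dict[str, int] = {}
    for r in sub.rows:
        a, b = r.pair()
        degrees[a] = degrees.get(a, 0) + 1
        degrees[b] = degrees.get(b, 0) + 1
    for v, d in degrees.items():
        if d > mult.f(v):
            raise ReductionInvariantError(
                f"reduction invariant broken: deg({v}) = {d} > 2m = {mult.f(v)}"
            )
    return sub


def verify_weight_relation(
    matching_weight: Fraction, selected: SelectedSubgraph, total_weight: Fraction
) -> bool:
    """Check weight(matching) = W + weight(selected 2m-matching).

    Run as a mandatory self-check after every solve; exact under rational
    weights (all arithmetic is on Fractions).
    """
    return matching_weight == total_weight + selected.weight


def decompose_to_chromosomes(selected: SelectedSubgraph, mult: MultiplicityMap) -> Genome:
    """Eulerian decomposition of the selected subgraph into chromosomes.

    Per connected component: all degrees even -> one Eulerian circuit -> one
    circular chromosome; 2k odd-degree vertices -> k edge-disjoint open trails
    (odd vertices paired lexicographically via virtual edges, which are cut
    out of the circuit afterwards) -> k linear chromosomes.  Isolated markers
    become length-1 linear chromosomes.  Each marker v then occurs
    (deg(v) + #trail-ends at v) / 2 <= m(v) times in total.
    """
    g = selected.graph()
    for v in g.nodes:
        if g.degree(v) > mult.f(v):
            raise ValueError(
                f"not a 2m-matching: deg({v}) = {g.degree(v)} > {mult.f(v)}"
            )
    chromosomes: list[Chromosome] = []
    for comp in sorted(nx.connected_components(g), key=min):
        comp = sorted(comp)
        if len(comp) == 1 and g.degree(comp[0]) == 0:
            chromosomes.append(Chromosome("linear", (comp[0],)))
            continue
        multi = nx.MultiGraph()
        multi.add_nodes_from(comp)
        for u, v in sorted(
            (min(a, b), max(a, b)) for a, b in g.subgraph(comp).edges
        ):
            multi.add_edge(u, v, virtual=False)
        odd = sorted(v for v in comp if multi.degree(v) % 2 == 1)
        for a, b in zip(odd[0::2], odd[1::2]):
            multi.add_edge(a, b, virtual=True)
        circuit = list(nx.eulerian_circuit(multi, source=comp[0], keys=True))
        virtual_at = [
            i for i, (u, v, k) in enumerate(circuit) if multi[u][v][k]["virtual"]
        ]
        if not virtual_at:
            seq = tuple(u for u, _, _ in circuit)
            assert len(seq) >= 3, "circular chromosome shorter than 3 is impossible"
            chromosomes.append(Chromosome("circular", seq))
        else:
            # Cut the closed walk at each virtual edge: k virtual edges yield
            # k open trails covering every real edge exactly once.
            cut = circuit[virtual_at[0] + 1 :] + circuit[: virtual_at[0] + 1]
            trails: list[list[tuple]] = [[]]
            for u, v, k in cut:
                if multi[u][v][k]["virtual"]:
                    trails.append([])
                else:
                    trails[-1].append((u, v))
            trails = [t for t in trails if t]
            for t in sorted(trails, key=lambda t: (t[0][0], t[-1][1])):
                seq = tuple([u for u, _ in t] + [t[-1][1]])
                chromosomes.append(Chromosome("linear", seq))
    genome = Genome(chromosomes=chromosomes)
    counts = genome.occurrence_counts()
    for v, c in counts.items():
        assert c <= mult[v], f"marker {v} occurs {c} > m = {mult[v]} times"
    return genome


def linearize(
    matrix: AdjacencyMatrix,
    mult: MultiplicityMap | None = None,
    self_check: bool = True,
) -> tuple[SelectedSubgraph, Genome, RunStats]:
    """End-to-end linearization of a degree-2 weighted adjacency matrix.

    Validates the instance, solves a maximum-weight 2m-matching per connected
    component of G_M via the gadget reduction (maximum-weight matching
    decomposes over components), verifies the weight identity, and decomposes
    the selected subgraph into chromosomes.

    Returns the selected row subset, one optimal genome, and run statistics.
    """
    if mult is None:
        mult = MultiplicityMap()
    validate_instance(matrix, mult).raise_if_invalid()
    g_m = matrix_to_graph(matrix)

    selected_ids: set[str] = set()
    matching_weight = Fraction(0)
    for comp in sorted(nx.connected_components(g_m), key=min):
        sub = g_m.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        gadget = build_gadget(sub, mult)
        matching = solve_max_weight_matching(gadget)
        matching_weight += matching.weight
        part = recover_f_matching(matching, gadget, matrix, mult)
        selected_ids.update(part.selected_row_ids)

    selected = SelectedSubgraph(parent=matrix, selected_row_ids=frozenset(selected_ids))
    if self_check and not verify_weight_relation(
        matching_weight, selected, matrix.total_weight
    ):
        raise ReductionInvariantError(
            f"weight relation violated: matching {matching_weight} != "
            f"W {matrix.total_weight} + selected {selected.weight}"
        )
    genome = decompose_to_chromosomes(selected, mult)
    n_lin, n_circ = genome.counts_by_kind()
    stats = RunStats(
        total_weight=matrix.total_weight,
        optimum_weight=selected.weight,
        rows_total=len(matrix.rows),
        rows_kept=len(selected.selected_row_ids),
        rows_discarded=len(matrix.rows) - len(selected.selected_row_ids),
        n_linear=n_lin,
        n_circular=n_circ,
        occurrence_histogram=genome.occurrence_counts(),
    )
    return selected, genome, stats
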