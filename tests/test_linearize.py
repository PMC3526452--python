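from fractions import Fraction

import networkx as nx
import pytest

from linchrom.core import (
    AdjacencyMatrix,
    MultiplicityMap,
    SelectedSubgraph,
    matrix_from_pairs,
    matrix_to_graph,
)
from linchrom.linearize import (
    build_gadget,
    decompose_to_chromosomes,
    linearize,
    recover_f_matching,
    solve_max_weight_matching,
    verify_weight_relation,
)
from linchrom.oracle import (
    brute_force_max_2m_matching,
    check_genome_realizes,
    is_2m_matching,
)
from linchrom.synth import generate_random_graph

from conftest import enumerate_max_matching_weight


class TestGadget:
    def test_single_edge_gadget_structure(self):
        """One edge {x, y} of weight 5 with m = 1 (f = 2): six vertices, five
        edges, all carrying the original weight."""
        m = matrix_from_pairs([("x", "y", 5)])
        gadget = build_gadget(matrix_to_graph(m), MultiplicityMap())
        copies = {v for v in gadget.graph.nodes if v[0] == "c"}
        ports = {v for v in gadget.graph.nodes if v[0] == "p"}
        assert copies == {("c", "x", 1), ("c", "x", 2), ("c", "y", 1), ("c", "y", 2)}
        assert len(ports) == 2
        assert gadget.graph.number_of_edges() == 5
        assert all(
            d["weight"] == Fraction(5) for _, _, d in gadget.graph.edges(data=True)
        )
        px, py = gadget.ports["r000001"]
        assert gadget.graph.has_edge(px, py)

    @pytest.mark.parametrize("seed", range(8))
    def test_size_formulas(self, seed):
        """|V'| = sum f(x) + 2|E|; |E'| = sum over edges of f(x) + f(y) + 1."""
        matrix, mult = generate_random_graph(7, 10, max_mult=2, seed=seed)
        g = matrix_to_graph(matrix)
        gadget = build_gadget(g, mult)
        n_expected = sum(mult.f(x) for x in g.nodes) + 2 * g.number_of_edges()
        e_expected = sum(mult.f(x) + mult.f(y) + 1 for x, y in g.edges)
        assert gadget.graph.number_of_nodes() == n_expected
        assert gadget.graph.number_of_edges() == e_expected

    def test_empty_edge_set_gives_isolated_copies(self):
        m = AdjacencyMatrix(markers=["a", "b"], rows=[])
        gadget = build_gadget(matrix_to_graph(m), MultiplicityMap())
        assert gadget.graph.number_of_nodes() == 4
        assert gadget.graph.number_of_edges() == 0


class TestMatching:
    def test_single_edge_matching_weight_matches_enumeration(self):
        m = matrix_from_pairs([("x", "y", 5)])
        gadget = build_gadget(matrix_to_graph(m), MultiplicityMap())
        assert enumerate_max_matching_weight(gadget.graph) == 10
        assert solve_max_weight_matching(gadget).weight == 10

    def test_triangle_matching_weight_matches_enumeration(self, triangle):
        gadget = build_gadget(matrix_to_graph(triangle), MultiplicityMap())
        assert enumerate_max_matching_weight(gadget.graph) == 6
        assert solve_max_weight_matching(gadget).weight == 6

    def test_empty_gadget_gives_empty_matching(self):
        m = AdjacencyMatrix(markers=["a"], rows=[])
        gadget = build_gadget(matrix_to_graph(m), MultiplicityMap())
        matching = solve_max_weight_matching(gadget)
        assert matching.weight == 0 and not matching.edges


class TestRecovery:
    def _solve(self, matrix, mult):
        g = matrix_to_graph(matrix)
        gadget = build_gadget(g, mult)
        matching = solve_max_weight_matching(gadget)
        selected = recover_f_matching(matching, gadget, matrix, mult)
        return matching, selected

    def test_triangle_keeps_all_rows(self, triangle):
        mult = MultiplicityMap()
        matching, selected = self._solve(triangle, mult)
        assert selected.selected_row_ids == {r.row_id for r in triangle.rows}
        assert selected.weight == 3
        assert verify_weight_relation(matching.weight, selected, triangle.total_weight)

    def test_star_unit_multiplicity_keeps_two_heaviest(self, star):
        mult = MultiplicityMap()
        matching, selected = self._solve(star, mult)
        assert selected.weight == 9
        assert verify_weight_relation(matching.weight, selected, star.total_weight)

    def test_star_doubled_center_keeps_all(self, star):
        mult = MultiplicityMap({"b": 2})
        matching, selected = self._solve(star, mult)
        assert selected.weight == 12
        assert selected.selected_row_ids == {r.row_id for r in star.rows}


class TestDecomposition:
    def test_cycle_becomes_one_circular_chromosome(self, triangle):
        sub = SelectedSubgraph(triangle, frozenset(r.row_id for r in triangle.rows))
        genome = decompose_to_chromosomes(sub, MultiplicityMap())
        assert [c.kind for c in genome.chromosomes] == ["circular"]
        assert set(genome.chromosomes[0].sequence) == {"a", "b", "c"}

    def test_path_becomes_one_linear_chromosome(self):
        m = matrix_from_pairs([("a", "b", 1), ("b", "c", 1)])
        sub = SelectedSubgraph(m, frozenset(r.row_id for r in m.rows))
        genome = decompose_to_chromosomes(sub, MultiplicityMap())
        assert [c.kind for c in genome.chromosomes] == ["linear"]
        assert genome.chromosomes[0].sequence in (("a", "b", "c"), ("c", "b", "a"))

    def test_figure_eight_is_one_circular_visiting_center_twice(self, figure_eight):
        matrix, mult = figure_eight
        sub = SelectedSubgraph(matrix, frozenset(r.row_id for r in matrix.rows))
        genome = decompose_to_chromosomes(sub, mult)
        assert [c.kind for c in genome.chromosomes] == ["circular"]
        assert genome.occurrence_counts()["v"] == 2
        assert check_genome_realizes(genome, sub, mult)

    def test_rejects_non_2m_matching(self, star):
        sub = SelectedSubgraph(star, frozenset(r.row_id for r in star.rows))
        with pytest.raises(ValueError, match="not a 2m-matching"):
            decompose_to_chromosomes(sub, MultiplicityMap())

    @pytest.mark.parametrize("seed", range(20))
    def test_component_parity_determines_chromosome_kinds(self, seed):
        """All-even component -> exactly one circular chromosome; a component
        with 2k odd-degree markers -> exactly k linear chromosomes."""
        matrix, mult = generate_random_graph(8, 9, max_mult=2, seed=seed)
        selected, genome, _ = linearize(matrix, mult)
        g = selected.graph()
        expected = []
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_edges() == 0:
                expected.append(("linear", 1))
                continue
            odd = sum(1 for v in comp if sub.degree(v) % 2 == 1)
            expected.append(("circular", 1) if odd == 0 else ("linear", odd // 2))
        n_lin, n_circ = genome.counts_by_kind()
        assert n_circ == sum(n for kind, n in expected if kind == "circular")
        assert n_lin == sum(n for kind, n in expected if kind == "linear")
        # each marker occurs (deg + trail-ends)/2 <= m times
        counts = genome.occurrence_counts()
        ends: dict[str, int] = {}
        for c in genome.chromosomes:
            if c.kind == "linear" and len(c) > 1:
                for v in (c.sequence[0], c.sequence[-1]):
                    ends[v] = ends.get(v, 0) + 1
        for v in g.nodes:
            if g.degree(v) > 0:
                assert counts[v] == (g.degree(v) + ends.get(v, 0)) // 2
            assert counts[v] <= mult[v]


class TestLinearize:
    def test_k4_optimum_is_a_four_cycle(self, k4):
        selected, genome, stats = linearize(k4)
        assert stats.optimum_weight == 4
        assert stats.rows_discarded == 2
        assert genome.counts_by_kind() == (0, 1)

    def test_empty_matrix_gives_singleton_chromosomes(self):
        m = AdjacencyMatrix(markers=["a", "b"], rows=[])
        selected, genome, stats = linearize(m)
        assert stats.optimum_weight == 0
        assert sorted(c.sequence for c in genome.chromosomes) == [("a",), ("b",)]
        assert all(c.kind == "linear" for c in genome.chromosomes)

    def test_invalid_instance_rejected(self):
        m = AdjacencyMatrix(
            markers=["a", "b"],
            rows=[
                matrix_from_pairs([("a", "b", 1)]).rows[0],
                matrix_from_pairs([("a", "b", 2)]).rows[0],
            ],
        )
        with pytest.raises(ValueError, match="duplicate"):
            linearize(m)

    @pytest.mark.parametrize("seed", range(40))
    def test_optimum_weight_matches_brute_force(self, seed):
        matrix, mult = generate_random_graph(
            5 + seed % 4, (seed * 7) % 12 + 2, max_mult=2, seed=seed
        )
        selected, genome, stats = linearize(matrix, mult)
        brute_weight, _ = brute_force_max_2m_matching(matrix, mult)
        assert stats.optimum_weight == brute_weight
        assert is_2m_matching(selected, mult)
        assert check_genome_realizes(genome, selected, mult)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_rows_and_multiplicity(self, seed):
        """Adding a row or raising any m(v) can never decrease the optimum."""
        matrix, _ = generate_random_graph(6, 8, max_mult=1, seed=seed)
        mult = MultiplicityMap()
        base = linearize(matrix, mult)[2].optimum_weight
        smaller = AdjacencyMatrix(markers=matrix.markers, rows=matrix.rows[:-1])
        assert linearize(smaller, mult)[2].optimum_weight <= base
        raised = MultiplicityMap({matrix.markers[0]: 2})
        assert linearize(matrix, raised)[2].optimum_weight >= base

    def test_fractional_weights_stay_exact(self):
        m = matrix_from_pairs(
            [("a", "b", Fraction(1, 3)), ("b", "c", Fraction(2, 7)), ("a", "c", Fraction(1, 2))]
        )
        _, _, stats = linearize(m)
        assert stats.optimum_weight == Fraction(1, 3) + Fraction(2, 7) + Fraction(1, 2)
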