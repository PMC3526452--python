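import itertools
from fractions import Fraction

import pytest

from linchrom.core import MultiplicityMap, matrix_from_pairs


@pytest.fixture
def triangle():
    """3-cycle a-b-c, unit weights, m = 1: every row keepable (one circular)."""
    return matrix_from_pairs([("a", "b", 1), ("a", "c", 1), ("b", "c", 1)])


@pytest.fixture
def k4():
    """Complete graph on 4 markers: optimum drops 2 of the 6 rows."""
    return matrix_from_pairs(
        [(a, b, 1) for a, b in itertools.combinations("abcd", 2)]
    )


@pytest.fixture
def star():
    """Star with center b and leaf weights 5, 4, 3."""
    return matrix_from_pairs([("b", "x", 5), ("b", "y", 4), ("b", "z", 3)])


@pytest.fixture
def figure_eight():
    """Two triangles sharing vertex v; realizable only with m(v) = 2."""
    matrix = matrix_from_pairs(
        [
            ("v", "a", 1),
            ("a", "b", 1),
            ("b", "v", 1),
            ("v", "c", 1),
            ("c", "d", 1),
            ("d", "v", 1),
        ]
    )
    return matrix, MultiplicityMap({"v": 2})


def enumerate_max_matching_weight(g):
    """Independent matching oracle: try every edge subset of a tiny graph."""
    edges = list(g.edges(data=True))
    best = Fraction(0)
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            endpoints = [u for u, _, _ in combo] + [v for _, v, _ in combo]
            if len(set(endpoints)) == 2 * len(combo):
                best = max(best, sum((d["weight"] for _, _, d in combo), Fraction(0)))
    return best
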