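"""Domain types shared by all modules, and the degree-2 matrix/graph identification.

A binary matrix whose rows each have exactly two 1-entries (an *adjacency
matrix*) is identified with a simple weighted graph: vertices are the marker
columns, edges are the rows.  All downstream algorithms operate on that graph.
Weights are kept as :class:`fractions.Fraction` internally so that optima can
be compared exactly; floats passed in are converted losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx

Weight = Union[int, float, Fraction]


def as_fraction(w: Weight) -> Fraction:
    """Convert a weight to an exact Fraction (floats converted losslessly)."""
    if isinstance(w, Fraction):
        return w
    if isinstance(w, int):
        return Fraction(w)
    return Fraction(w)  # exact binary expansion of the float


@dataclass(frozen=True)
class Row:
    """One matrix row: an unordered set of 2 (or, for oracles, 3) marker columns.

    A degree-2 row is an *adjacency* between two markers; a degree-3 row is an
    *interval* of three markers, accepted only by the brute-force oracles.
    """

    row_id: str
    columns: frozenset[str]
    weight: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", frozenset(self.columns))
        object.__setattr__(self, "weight", as_fraction(self.weight))

    @property
    def degree(self) -> int:
        return len(self.columns)

    def pair(self) -> tuple[str, str]:
        """The two endpoints of a degree-2 row, lexicographically ordered."""
        if len(self.columns) != 2:
            raise ValueError(f"row {self.row_id} has degree {len(self.columns)}, not 2")
        a, b = sorted(self.columns)
        return a, b


@dataclass
class AdjacencyMatrix:
    """A weighted binary matrix: columns are markers, rows are adjacencies/intervals.

    Markers with no incident row are allowed (isolated columns); every marker
    referenced by a row must be declared.
    """

    markers: list[str]
    rows: list[Row]

    @property
    def degree(self) -> int:
        """Maximum row degree (0 for an empty row list)."""
        return max((r.degree for r in self.rows), default=0)

    @property
    def total_weight(self) -> Fraction:
        return sum((r.weight for r in self.rows), Fraction(0))

    def row_by_id(self, row_id: str) -> Row:
        for r in self.rows:
            if r.row_id == row_id:
                return r
        raise KeyError(row_id)


class MultiplicityMap:
    """Maximum copy number m(c) >= 1 per marker; unlisted markers default to 1.

    m(c) bounds how many times marker c may occur in the reconstructed genome;
    the matching reduction uses the doubled capacity f(c) = 2*m(c).
    """

    def __init__(self, values: Mapping[str, int] | None = None) -> None:
        self._values: dict[str, int] = {}
        if values:
            for k, v in values.items():
                v = int(v)
                if v < 1:
                    raise ValueError(f"multiplicity m({k}) = {v} < 1")
                self._values[k] = v

    def __getitem__(self, marker: str) -> int:
        return self._values.get(marker, 1)

    def f(self, marker: str) -> int:
        """Doubled capacity 2*m(marker) used by the gadget reduction."""
        return 2 * self[marker]

    def items(self) -> Iterable[tuple[str, int]]:
        return self._values.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiplicityMap):
            return NotImplemented
        explicit = {k: v for k, v in self._values.items() if v != 1}
        other_explicit = {k: v for k, v in other._values.items() if v != 1}
        return explicit == other_explicit

    def __repr__(self) -> str:
        return f"MultiplicityMap({self._values!r})"


@dataclass
class SelectedSubgraph:
    """A subset of rows of a degree-2 matrix, viewed as a spanning subgraph of G_M."""

    parent: AdjacencyMatrix
    selected_row_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.selected_row_ids = frozenset(self.selected_row_ids)
        known = {r.row_id for r in self.parent.rows}
        unknown = self.selected_row_ids - known
        if unknown:
            raise ValueError(f"selected row ids not in parent matrix: {sorted(unknown)}")

    @property
    def rows(self) -> list[Row]:
        return [r for r in self.parent.rows if r.row_id in self.selected_row_ids]

    @property
    def weight(self) -> Fraction:
        return sum((r.weight for r in self.rows), Fraction(0))

    def graph(self) -> nx.Graph:
        """Spanning subgraph of G_M induced by the selected rows."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.parent.markers))
        for r in self.rows:
            a, b = r.pair()
            g.add_edge(a, b, weight=r.weight, row_id=r.row_id)
        return g


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: a marker sequence, either linear or circular."""

    kind: str  # "linear" | "circular"
    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "circular"):
            raise ValueError(f"unknown chromosome kind {self.kind!r}")
        if len(self.sequence) < 1:
            raise ValueError("empty chromosome")
        object.__setattr__(self, "sequence", tuple(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def adjacencies(self) -> list[tuple[str, str]]:
        """Consecutive unordered marker pairs; circular chromosomes include the wrap."""
        pairs = [
            (min(a, b), max(a, b))
            for a, b in zip(self.sequence, self.sequence[1:])
        ]
        if self.kind == "circular" and len(self.sequence) > 1:
            a, b = self.sequence[-1], self.sequence[0]
            pairs.append((min(a, b), max(a, b)))
        return pairs


@dataclass
class Genome:
    """An ordered collection of chromosomes realizing a selected row subset."""

    chromosomes: list[Chromosome]

    def occurrence_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for chrom in self.chromosomes:
            for m in chrom.sequence:
                counts[m] = counts.get(m, 0) + 1
        return counts

    def adjacency_multiset(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for chrom in self.chromosomes:
            for pair in chrom.adjacencies():
                counts[pair] = counts.get(pair, 0) + 1
        return counts

    def counts_by_kind(self) -> tuple[int, int]:
        """(number of linear chromosomes, number of circular chromosomes)."""
        lin = sum(1 for c in self.chromosomes if c.kind == "linear")
        return lin, len(self.chromosomes) - lin


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str) -> None:
        self.violations.append(Violation(code, message))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            detail = "; ".join(str(v) for v in self.violations)
            raise ValueError(f"invalid instance: {detail}")


def validate_instance(
    matrix: AdjacencyMatrix, mult: MultiplicityMap | None = None
) -> ValidationReport:
    """Check structural invariants of an instance; returns a report of violations.

    Flags duplicate marker ids, duplicate row column-sets, rows of degree
    outside {2, 3}, self-adjacencies, non-positive weights, and rows referring
    to undeclared markers.  Multiplicities below 1 are rejected at
    :class:`MultiplicityMap` construction already.
    """
    report = ValidationReport()
    seen_markers: set[str] = set()
    for m in matrix.markers:
        if not m or any(ch.isspace() for ch in m):
            report.add("bad-marker-id", f"marker id {m!r} is empty or contains whitespace")
        if m in seen_markers:
            report.add("duplicate-marker", f"marker {m!r} declared more than once")
        seen_markers.add(m)

    seen_column_sets: set[frozenset[str]] = set()
    seen_row_ids: set[str] = set()
    for r in matrix.rows:
        if r.row_id in seen_row_ids:
            report.add("duplicate-row-id", f"row id {r.row_id!r} appears twice")
        seen_row_ids.add(r.row_id)
        if r.degree < 2:
            report.add(
                "self-adjacency",
                f"row {r.row_id}: fewer than 2 distinct columns (self-adjacency)",
            )
        elif r.degree > 3:
            report.add("bad-degree", f"row {r.row_id}: degree {r.degree} not in {{2, 3}}")
        if r.columns in seen_column_sets:
            report.add(
                "duplicate-row",
                f"row {r.row_id}: duplicate row column set {sorted(r.columns)}",
            )
        seen_column_sets.add(r.columns)
        if r.weight <= 0:
            report.add("non-positive-weight", f"row {r.row_id}: weight {r.weight} <= 0")
        undeclared = r.columns - seen_markers
        if undeclared - {m for m in matrix.markers}:
            report.add(
                "undeclared-marker",
                f"row {r.row_id}: undeclared markers {sorted(r.columns - set(matrix.markers))}",
            )
    return report


def matrix_to_graph(matrix: AdjacencyMatrix) -> nx.Graph:
    """Identify a degree-2 matrix with its graph G_M.

    Vertices are all declared markers (including isolated ones); each row
    {a, b} becomes the edge a-b carrying the row weight and a ``row_id``
    back-pointer.  Rejects matrices containing degree-3 rows.
    """
    if matrix.degree > 2:
        raise ValueError("degree>2 not supported by linearizer")
    g = nx.Graph()
    g.add_nodes_from(sorted(matrix.markers))
    for r in matrix.rows:
        a, b = r.pair()
        g.add_edge(a, b, weight=r.weight, row_id=r.row_id)
    return g


def graph_to_matrix(g: nx.Graph) -> AdjacencyMatrix:
    """Inverse identification: a simple weighted graph becomes a degree-2 matrix.

    Edges are emitted in lexicographic order with generated row ids; the
    round-trip graph -> matrix -> graph is the identity up to edge attributes.
    """
    markers = sorted(g.nodes)
    rows = []
    for i, (a, b) in enumerate(sorted((min(u, v), max(u, v)) for u, v in g.edges)):
        data = g[a][b]
        rows.append(
            Row(
                row_id=data.get("row_id", f"r{i + 1:06d}"),
                columns=frozenset({a, b}),
                weight=as_fraction(data.get("weight", 1)),
            )
        )
    return AdjacencyMatrix(markers=markers, rows=rows)


def matrix_from_pairs(
    pairs: Sequence[tuple[str, str, Weight]],
    markers: Sequence[str] | None = None,
) -> AdjacencyMatrix:
    """Convenience constructor from (a, b, weight) triples.

    Markers default to the union of endpoints; extra isolated markers may be
    declared explicitly.
    """
    rows = []
    referenced: set[str] = set()
    for i, (a, b, w) in enumerate(pairs):
        rows.append(Row(f"r{i + 1:06d}", frozenset({a, b}), as_fraction(w)))
        referenced.update((a, b))
    if markers is None:
        marker_list = sorted(referenced)
    else:
        marker_list = list(markers)
    return AdjacencyMatrix(markers=marker_list, rows=rows)
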