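"""Plain-text file formats: adjacency TSV, multiplicity TSV, genome format.

All formats are UTF-8, tab-separated where columnar, with ``#`` comment lines
and blank lines ignored.  Readers reject malformed input with the offending
line number rather than repairing it; writers emit canonical files that their
readers round-trip exactly.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Iterable, TextIO, Union

from linchrom.core import (
    AdjacencyMatrix,
    Chromosome,
    Genome,
    MultiplicityMap,
    Row,
)

PathLike = Union[str, Path]

GENOME_HEADER = "#linchrom-genome v1"


class FormatError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


def _content_lines(text: str) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _parse_weight(token: str, lineno: int) -> Fraction:
    try:
        w = Fraction(token)
    except (ValueError, ZeroDivisionError) as exc:
        raise FormatError(f"line {lineno}: non-numeric weight {token!r}") from exc
    if w <= 0:
        raise FormatError(f"line {lineno}: weight {token} must be positive")
    return w


def read_adjacencies(path: PathLike, allow_degree3: bool = False) -> AdjacencyMatrix:
    """Read an adjacency TSV: ``a<TAB>b<TAB>weight`` per row.

    The degree-3 dialect ``a<TAB>b<TAB>c<TAB>weight`` is accepted only when
    ``allow_degree3`` is set (brute-force oracle inputs).  Row ids are
    ``r000001...`` in file order.  Weights may be decimals or rationals
    (``3/4``).
    """
    text = Path(path).read_text(encoding="utf-8")
    rows: list[Row] = []
    markers: set[str] = set()
    for lineno, line in _content_lines(text):
        fields = line.split("\t")
        if len(fields) == 3:
            cols, wtok = fields[:2], fields[2]
        elif len(fields) == 4 and allow_degree3:
            cols, wtok = fields[:3], fields[3]
        else:
            raise FormatError(
                f"line {lineno}: expected {'3 or 4' if allow_degree3 else '3'} "
                f"tab-separated fields, got {len(fields)}"
            )
        if len(set(cols)) != len(cols):
            raise FormatError(f"line {lineno}: repeated marker (self-adjacency)")
        w = _parse_weight(wtok, lineno)
        markers.update(cols)
        rows.append(Row(f"r{len(rows) + 1:06d}", frozenset(cols), w))
    return AdjacencyMatrix(markers=sorted(markers), rows=rows)


def _format_weight(w: Fraction) -> str:
    if w.denominator == 1:
        return str(w.numerator)
    # decimal rendering when exact, else exact rational
    num, den = w.numerator, w.denominator
    d = den
    twos = fives = 0
    while d % 2 == 0:
        d //= 2
        twos += 1
    while d % 5 == 0:
        d //= 5
        fives += 1
    if d == 1:
        digits = max(twos, fives)
        scaled = num * 10**digits // den
        s = f"{scaled:0{digits + 1}d}"
        return f"{s[:-digits]}.{s[-digits:]}"
    return f"{num}/{den}"


def write_adjacencies(matrix: AdjacencyMatrix, path: PathLike) -> None:
    """Write the adjacency TSV (degree-3 rows use the 4-column dialect)."""
    lines = ["# adjacency matrix: marker_a\tmarker_b[\tmarker_c]\tweight"]
    for r in matrix.rows:
        cols = sorted(r.columns)
        lines.append("\t".join(cols + [_format_weight(r.weight)]))
    isolated = sorted(set(matrix.markers) - {c for r in matrix.rows for c in r.columns})
    if isolated:
        lines.append("# isolated markers: " + " ".join(isolated))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_multiplicities(path: PathLike) -> MultiplicityMap:
    """Read the multiplicity TSV ``marker<TAB>max_copies``; unlisted default to 1."""
    text = Path(path).read_text(encoding="utf-8")
    values: dict[str, int] = {}
    for lineno, line in _content_lines(text):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        marker, mtok = fields
        try:
            m = int(mtok)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer multiplicity {mtok!r}") from exc
        if m < 1:
            raise FormatError(f"line {lineno}: multiplicity {m} < 1")
        values[marker] = m
    return MultiplicityMap(values)


def write_multiplicities(mult: MultiplicityMap, path: PathLike) -> None:
    lines = ["# multiplicities: marker\tmax_copies"]
    for marker, m in sorted(mult.items()):
        lines.append(f"{marker}\t{m}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def canonical_chromosome(chrom: Chromosome) -> Chromosome:
    """Canonical form: circular sequences are rotated/reflected to start at the
    smallest marker with the lexicographically minimal continuation."""
    if chrom.kind != "circular" or len(chrom) == 1:
        return chrom
    seq = chrom.sequence
    n = len(seq)
    candidates = []
    for direction in (seq, tuple(reversed(seq))):
        for start in range(n):
            candidates.append(direction[start:] + direction[:start])
    return Chromosome("circular", min(candidates))


def write_genome(genome: Genome, path_or_file: PathLike | TextIO) -> None:
    """Write the genome format: ``C m1 m2 m3`` (circular) / ``L m1 m2`` (linear).

    Circular chromosomes are canonicalized (rotation and direction) so that
    write/read round-trips are stable.
    """
    lines = [GENOME_HEADER]
    for chrom in genome.chromosomes:
        c = canonical_chromosome(chrom)
        flag = "C" if c.kind == "circular" else "L"
        lines.append(" ".join([flag] + list(c.sequence)))
    text = "\n".join(lines) + "\n"
    if isinstance(path_or_file, (str, Path)):
        Path(path_or_file).write_text(text, encoding="utf-8")
    else:
        path_or_file.write(text)


def read_genome(path: PathLike) -> Genome:
    text = Path(path).read_text(encoding="utf-8")
    chromosomes: list[Chromosome] = []
    for lineno, line in _content_lines(text):
        fields = line.split()
        flag, seq = fields[0], fields[1:]
        if flag not in ("C", "L"):
            raise FormatError(f"line {lineno}: unknown chromosome flag {flag!r}")
        if not seq:
            raise FormatError(f"line {lineno}: empty chromosome")
        chromosomes.append(
            Chromosome("circular" if flag == "C" else "linear", tuple(seq))
        )
    return Genome(chromosomes=chromosomes)


def write_selected_rows(row_ids: Iterable[str], path: PathLike) -> None:
    lines = ["# selected row ids"] + sorted(row_ids)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
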