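"""Deterministic synthetic instances with known structure.

Two generators: ``generate_planted`` builds a random genome first and derives
its adjacency rows from it, optionally adding lighter conflicting noise rows
so that the planted rows remain the unique optimum (*strict mode*);
``generate_random_graph`` draws an unconstrained uniform simple graph for
fuzzing against the brute-force oracles.

Weights are rationals with denominator 10^4 so all downstream arithmetic
stays exact.  Everything is driven by a single integer seed; identical
parameters give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction

from linchrom.core import (
    AdjacencyMatrix,
    Chromosome,
    Genome,
    MultiplicityMap,
    Row,
)

WEIGHT_DENOM = 10_000


@dataclass
class SynthParams:
    """Parameters of a planted-genome instance.

    ``true_weight_range`` and ``noise_weight_range`` are half-open intervals
    (lo, hi]; *strict mode* (every noise row strictly lighter than every
    planted row, noise attached only to saturated markers) holds whenever
    ``noise_weight_range[1] < true_weight_range[0]``.
    """

    n_markers: int = 8
    n_chromosomes: int = 1
    circular_fraction: float = 0.5
    duplicated_fraction: float = 0.0
    true_weight_range: tuple[float, float] = (1.0, 2.0)
    noise_edge_count: int = 0
    noise_weight_range: tuple[float, float] = (0.0, 0.5)
    seed: int = 0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 1 <= self.n_chromosomes <= self.n_markers:
            raise ValueError("need 1 <= n_chromosomes <= n_markers")
        if not 0.0 <= self.circular_fraction <= 1.0:
            raise ValueError("circular_fraction must be in [0, 1]")
        if not 0.0 <= self.duplicated_fraction <= 1.0:
            raise ValueError("duplicated_fraction must be in [0, 1]")
        lo, hi = self.true_weight_range
        if not 0 < lo <= hi:
            raise ValueError("true_weight_range must satisfy 0 < lo <= hi")
        if self.noise_edge_count < 0:
            raise ValueError("noise_edge_count must be >= 0")
        nlo, nhi = self.noise_weight_range
        if self.noise_edge_count > 0 and not 0 <= nlo <= nhi:
            raise ValueError("noise_weight_range must satisfy 0 <= lo <= hi")
        if self.strict and self.noise_edge_count > 0 and not nhi < lo:
            raise ValueError(
                "strict mode requires every noise weight below every true weight "
                f"(noise hi {nhi} >= true lo {lo})"
            )


def _draw_weight(rng: random.Random, lo: float, hi: float) -> Fraction:
    """Uniform rational in (lo, hi] with denominator 10^4."""
    lo_n = int(lo * WEIGHT_DENOM)
    hi_n = int(hi * WEIGHT_DENOM)
    if hi_n <= lo_n:
        hi_n = lo_n + 1
    return Fraction(rng.randint(lo_n + 1, hi_n), WEIGHT_DENOM)


def _marker_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _build_chromosomes(
    rng: random.Random, params: SynthParams, markers: list[str], duplicated: set[str]
) -> list[Chromosome]:
    """Random genome: split a shuffled marker pool into chromosomes.

    Duplicated markers contribute two copies to the pool; both copies land in
    random positions (possibly on one chromosome).  Equal consecutive copies
    are separated by a local reshuffle since self-adjacencies are not
    representable as matrix rows.
    """
    pool = list(markers) + sorted(duplicated)
    rng.shuffle(pool)
    # chromosome sizes: each >= 1, circular ones >= 3
    n_circ = round(params.circular_fraction * params.n_chromosomes)
    kinds = ["circular"] * n_circ + ["linear"] * (params.n_chromosomes - n_circ)
    sizes = [3 if k == "circular" else 1 for k in kinds]
    spare = len(pool) - sum(sizes)
    if spare < 0:
        raise ValueError(
            f"impossible request: {n_circ} circular chromosomes need at least "
            f"{sum(sizes)} marker copies, only {len(pool)} available"
        )
    for _ in range(spare):
        sizes[rng.randrange(len(sizes))] += 1

    chromosomes: list[Chromosome] = []
    idx = 0
    for kind, size in zip(kinds, sizes):
        seq = pool[idx : idx + size]
        idx += size
        for attempt in range(100):
            bad = any(a == b for a, b in zip(seq, seq[1:]))
            if kind == "circular" and len(seq) > 1 and seq[0] == seq[-1]:
                bad = True
            if kind == "circular" and len(set(seq)) < 3 <= len(seq):
                bad = True  # e.g. (a, b, a, b): wrap would duplicate a row
            if not bad:
                break
            rng.shuffle(seq)
        else:
            raise ValueError(
                "impossible request: cannot arrange duplicated markers without "
                "self-adjacencies; lower duplicated_fraction or raise n_markers"
            )
        chromosomes.append(Chromosome(kind, tuple(seq)))
    return chromosomes


def generate_planted(
    params: SynthParams,
) -> tuple[AdjacencyMatrix, MultiplicityMap, Genome]:
    """Planted-genome instance: rows are the genome's own adjacencies plus noise.

    The genome's adjacency multiset (deduplicated) becomes the planted rows
    with weights from ``true_weight_range``.  Noise rows are sampled without
    replacement from non-planted marker pairs; in strict mode only pairs of
    markers already saturated in the planted genome (degree = 2m) are
    eligible, so every noise row conflicts with the planted solution and the
    planted row set is the unique maximum-weight 2m-matching.
    """
    rng = random.Random(params.seed)
    markers = _marker_names(params.n_markers)
    n_dup = round(params.duplicated_fraction * params.n_markers)
    duplicated = set(rng.sample(markers, n_dup))
    mult = MultiplicityMap({m: 2 for m in sorted(duplicated)})

    # A duplicated marker could realize the same adjacency twice (once per
    # copy); such a genome would not be recoverable from its deduplicated row
    # set, so redraw until every adjacency occurs exactly once.
    for _ in range(200):
        chromosomes = _build_chromosomes(rng, params, markers, duplicated)
        genome = Genome(chromosomes=chromosomes)
        if all(c == 1 for c in genome.adjacency_multiset().values()):
            break
    else:
        raise ValueError(
            "impossible request: could not build a genome with distinct "
            "adjacencies; lower duplicated_fraction or raise n_markers"
        )

    planted_pairs = sorted(genome.adjacency_multiset())
    rows = [
        Row(f"r{i + 1:06d}", frozenset(p), _draw_weight(rng, *params.true_weight_range))
        for i, p in enumerate(planted_pairs)
    ]

    if params.noise_edge_count > 0:
        degree: dict[str, int] = {m: 0 for m in markers}
        for a, b in planted_pairs:
            degree[a] += 1
            degree[b] += 1
        if params.strict:
            eligible = [m for m in markers if degree[m] == 2 * mult[m]]
        else:
            eligible = markers
        taken = set(map(frozenset, planted_pairs))
        candidates = [
            frozenset(p)
            for p in itertools.combinations(sorted(eligible), 2)
            if frozenset(p) not in taken
        ]
        if len(candidates) < params.noise_edge_count:
            raise ValueError(
                f"impossible request: only {len(candidates)} eligible noise pairs "
                f"exist, {params.noise_edge_count} requested"
            )
        chosen = rng.sample(candidates, params.noise_edge_count)
        for j, cols in enumerate(sorted(chosen, key=sorted)):
            rows.append(
                Row(
                    f"n{j + 1:06d}",
                    cols,
                    _draw_weight(rng, *params.noise_weight_range),
                )
            )

    matrix = AdjacencyMatrix(markers=markers, rows=rows)
    return matrix, mult, genome


def planted_row_ids(matrix: AdjacencyMatrix) -> frozenset[str]:
    """Row ids of the planted (non-noise) rows of a generated instance."""
    return frozenset(r.row_id for r in matrix.rows if r.row_id.startswith("r"))


def generate_blocked(
    n_blocks: int,
    block_params: SynthParams,
    extra_rows: int = 0,
    seed: int = 0,
    target_rows: int | None = None,
) -> tuple[AdjacencyMatrix, MultiplicityMap]:
    """Large instance made of independent linkage groups.

    Real adjacency datasets decompose into many moderate connected components
    (one per replicon or linkage group); this assembles ``n_blocks``
    planted-genome instances under disjoint marker namespaces and then adds
    ``extra_rows`` random within-block rows with weights in (0, 1], emulating
    weak conflicting adjacency candidates.  Used for scalability testing.
    """
    rng = random.Random(seed)
    markers: list[str] = []
    rows: list[Row] = []
    mult_values: dict[str, int] = {}
    block_markers: list[list[str]] = []
    existing: set[frozenset[str]] = set()
    for b in range(n_blocks):
        params = SynthParams(
            **{
                **block_params.__dict__,
                "seed": (seed * 1_000_003 + b) % (2**31),
            }
        )
        matrix, mult, _ = generate_planted(params)
        rename = {m: f"b{b:04d}.{m}" for m in matrix.markers}
        markers += [rename[m] for m in matrix.markers]
        block_markers.append([rename[m] for m in matrix.markers])
        for r in matrix.rows:
            cols = frozenset(rename[c] for c in r.columns)
            rows.append(Row(f"b{b:04d}.{r.row_id}", cols, r.weight))
            existing.add(cols)
        for m, v in mult.items():
            mult_values[rename[m]] = v
    if target_rows is not None:
        extra_rows = max(0, target_rows - len(rows))
    added = 0
    while added < extra_rows:
        blk = block_markers[rng.randrange(n_blocks)]
        cols = frozenset(rng.sample(blk, 2))
        if cols in existing:
            continue
        existing.add(cols)
        rows.append(Row(f"x{added + 1:06d}", cols, _draw_weight(rng, 0.0, 1.0)))
        added += 1
    return AdjacencyMatrix(markers=markers, rows=rows), MultiplicityMap(mult_values)


def generate_random_graph(
    n_vertices: int, n_edges: int, max_mult: int = 1, seed: int = 0
) -> tuple[AdjacencyMatrix, MultiplicityMap]:
    """Uniform simple graph with uniform rational weights in (0, 1].

    Multiplicities are uniform in {1, .., max_mult}; deterministic per seed.
    """
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    max_edges = n_vertices * (n_vertices - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges = {n_edges} exceeds C(n, 2) = {max_edges}")
    rng = random.Random(seed)
    markers = _marker_names(n_vertices)
    pairs = rng.sample(list(itertools.combinations(markers, 2)), n_edges)
    rows = [
        Row(f"r{i + 1:06d}", frozenset(p), _draw_weight(rng, 0.0, 1.0))
        for i, p in enumerate(sorted(pairs))
    ]
    mult = MultiplicityMap(
        {m: rng.randint(1, max_mult) for m in markers} if max_mult > 1 else {}
    )
    return AdjacencyMatrix(markers=markers, rows=rows), mult
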