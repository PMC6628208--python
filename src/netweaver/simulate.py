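"""Seeded synthetic multi-screen fixtures with exact planted truth.

Everything downstream of data upload — resolution, wheel merging, attribute
mapping, filtration, partitioning, enrichment — is testable offline against
fixtures built here.  The generators emulate the combinatorial structure of
a multi-core target-list study:

* ``generate_datasets`` plants K core genes with target lists of controlled
  pairwise and full overlap, by direct assignment of exclusive blocks (never
  rejection sampling), so the planted truth is exact;
* ``generate_expression_table`` plants a "highly expressed" subpopulation —
  a designated gene set drawn high at an elevated rate against a background
  rate — on the correct side of the classification threshold;
* ``generate_backend_tables`` writes resolver mapping tables in which a
  configurable fraction of submitted identifiers are stale aliases the
  resolver must update, plus an interaction table with feedback cycles among
  network members (which survive degree filtration) and leaf edges to
  outsiders (which do not).

Default parameters mirror the scale of the motivating study: three cores
with 1072, 3692 and 309 targets in a 15682-gene universe, a 23-gene
three-way co-regulated block, a background high-expression rate of 8% and a
planted rate of 35%.  Every generator is a pure function of its spec and
seed: same seed, byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import Dataset
from .tabular_io import RawTable, write_table

__all__ = [
    "OverlapSpec",
    "ExpressionSpec",
    "InteractionSpec",
    "DatasetTruth",
    "BackendTruth",
    "generate_datasets",
    "generate_expression_table",
    "generate_backend_tables",
]


def _gene_id(i: int) -> str:
    return f"SYN{i + 1:07d}"


@dataclass(frozen=True)
class OverlapSpec:
    """Planted overlap design for K core target lists.

    ``pairwise_overlaps`` maps a core-index pair to the *total* overlap
    |targets_i ∩ targets_j| (including the full overlap); ``full_overlap``
    is the size of the block shared by all cores.  Inclusion–exclusion must
    yield non-negative exclusive block sizes that fit in the universe.
    """

    n_cores: int = 3
    per_core_sizes: tuple[int, ...] = (1072, 3692, 309)
    pairwise_overlaps: Mapping[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 1): 150, (0, 2): 40, (1, 2): 60}
    )
    full_overlap: int = 23
    universe_size: int = 15682
    seed: int = 0
    organism: str = "Synthetica exempli"
    techniques: tuple[str, ...] = ("DamID",)

    def pair(self, i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        return int(self.pairwise_overlaps.get(key, 0))

    def exclusive_blocks(self) -> dict[frozenset[int], int]:
        """Exclusive block sizes by inclusion–exclusion; raises if inconsistent."""
        if len(self.per_core_sizes) != self.n_cores:
            raise ValueError("per_core_sizes length must equal n_cores")
        blocks: dict[frozenset[int], int] = {}
        full = self.full_overlap if self.n_cores >= 3 else 0
        if self.n_cores >= 3:
            blocks[frozenset(range(self.n_cores))] = full
        for i in range(self.n_cores):
            for j in range(i + 1, self.n_cores):
                excl = self.pair(i, j) - full
                if excl < 0:
                    raise ValueError(f"pairwise overlap ({i},{j}) smaller than full overlap")
                if excl or self.pair(i, j):
                    blocks[frozenset((i, j))] = excl
        for i, size in enumerate(self.per_core_sizes):
            shared = full + sum(
                blocks.get(frozenset((i, j)), 0) for j in range(self.n_cores) if j != i
            )
            excl = size - shared
            if excl < 0:
                raise ValueError(f"core {i} size {size} smaller than its planted overlaps")
            blocks[frozenset((i,))] = excl
        total = sum(blocks.values())
        if total > self.universe_size:
            raise ValueError(f"planted design needs {total} genes, universe has {self.universe_size}")
        return {k: v for k, v in blocks.items() if v > 0 or len(k) == self.n_cores}


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted high-expression structure around a classification threshold."""

    high_fraction_background: float = 0.08
    high_fraction_planted: float = 0.35
    threshold: float = 50.0
    high_max: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.high_fraction_background, self.high_fraction_planted):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.high_max < self.threshold:
            raise ValueError("high_max must be >= threshold")


@dataclass(frozen=True)
class InteractionSpec:
    """Planted curated-interaction structure for the backend tables."""

    members: tuple[str, ...]  # network member primary ids
    n_feedback_cycles: int = 2
    n_leaf_edges: int = 3


@dataclass(frozen=True)
class DatasetTruth:
    """Exact planted truth of a generated multi-screen design."""

    core_records: tuple[tuple[str, str], ...]  # (primary id, symbol) per core
    blocks: dict[frozenset[str], frozenset[str]]  # core-id subset -> exclusive members
    universe: tuple[str, ...]

    @property
    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.blocks.values():
            out |= members
        return frozenset(out)

    def targets_of(self, core_id: str) -> frozenset[str]:
        out: set[str] = set()
        for key, members in self.blocks.items():
            if core_id in key:
                out |= members
        return frozenset(out)


@dataclass(frozen=True)
class BackendTruth:
    alias_of: dict[str, str]  # primary id -> stale submitted alias
    feedback_pairs: tuple[tuple[str, str], ...]
    leaf_edges: tuple[tuple[str, str], ...]


def generate_datasets(
    spec: OverlapSpec, out_dir: str | None = None
) -> tuple[list[Dataset], DatasetTruth]:
    """Generate one target-list dataset per core with planted overlaps.

    Exclusive blocks are carved from a seeded permutation of the universe by
    direct assignment, so the truth record is exact.  With ``out_dir`` set,
    one single-column CSV per dataset is also written
    (``<out_dir>/<name>.csv``, header ``GeneID``).
    """
    rng = np.random.default_rng(spec.seed)
    universe = tuple(_gene_id(i) for i in range(spec.universe_size))
    order = rng.permutation(spec.universe_size)

    sizes = spec.exclusive_blocks()
    block_keys = sorted(sizes, key=lambda k: (len(k), sorted(k)))
    cursor = 0
    blocks_by_idx: dict[frozenset[int], frozenset[str]] = {}
    for key in block_keys:
        size = sizes[key]
        blocks_by_idx[key] = frozenset(universe[j] for j in order[cursor : cursor + size])
        cursor += size

    cores = tuple(
        (f"SYNCORE{i + 1:02d}", f"core{i + 1}") for i in range(spec.n_cores)
    )
    core_ids = [primary for primary, _ in cores]
    blocks = {
        frozenset(core_ids[i] for i in key): members
        for key, members in blocks_by_idx.items()
    }
    truth = DatasetTruth(cores, blocks, universe)

    datasets: list[Dataset] = []
    for i, (primary, symbol) in enumerate(cores):
        targets = sorted(truth.targets_of(primary))
        rng_i = np.random.default_rng(spec.seed * 1000 + i + 1)
        targets = [targets[j] for j in rng_i.permutation(len(targets))]
        technique = spec.techniques[i % len(spec.techniques)]
        datasets.append(
            Dataset(
                name=f"{symbol}_{technique}",
                organism=spec.organism,
                core_symbol=symbol,
                technique=technique,
                identifiers=tuple(targets),
            )
        )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for ds in datasets:
            table = RawTable(("GeneID",), tuple((g,) for g in ds.identifiers))
            write_table(table, os.path.join(out_dir, f"{ds.name}.csv"))
    return datasets, truth


def generate_expression_table(
    universe: Sequence[str],
    spec: ExpressionSpec,
    planted_set: Sequence[str] | frozenset[str] = frozenset(),
) -> tuple[RawTable, frozenset[str]]:
    """Expression table (columns ``GeneID,RPKM``) with a planted high set.

    Genes in ``planted_set`` are drawn "high" with probability
    ``high_fraction_planted``, the rest with ``high_fraction_background``;
    high values land in [threshold, high_max], low values strictly below the
    threshold.  Returns the table and the exact set of high genes.
    """
    planted = set(planted_set)
    if not planted <= set(universe):
        raise ValueError("planted_set must be a subset of the universe")
    rng = np.random.default_rng(spec.seed)
    n = len(universe)
    u = rng.random(n)
    is_planted = np.fromiter((g in planted for g in universe), dtype=bool, count=n)
    cutoff = np.where(is_planted, spec.high_fraction_planted, spec.high_fraction_background)
    is_high = u < cutoff
    low = np.round(rng.uniform(0.0, spec.threshold - 0.01, size=n), 2)
    high = np.round(rng.uniform(spec.threshold, spec.high_max, size=n), 2)
    values = np.where(is_high, high, low)
    rows = tuple(
        (gene, format(values[i], ".2f")) for i, gene in enumerate(universe)
    )
    table = RawTable(("GeneID", "RPKM"), rows)
    high_set = frozenset(g for i, g in enumerate(universe) if is_high[i])
    return table, high_set


def generate_backend_tables(
    universe: Sequence[str],
    stale_fraction: float = 0.0,
    interaction_spec: InteractionSpec | None = None,
    cores: Sequence[tuple[str, str]] = (),
    seed: int = 0,
    out_dir: str | None = None,
) -> tuple[RawTable, RawTable, BackendTruth]:
    """Resolver mapping and interaction tables with planted structure.

    A ``stale_fraction`` of universe genes get a stale submitted alias
    (``OLD...``) whose mapping row updates it to the current primary id; the
    rest map to themselves.  The interaction table carries the planted
    feedback 2-cycles (genetic) among the given network members and leaf
    edges (physical) from members to outsider genes absent from the network.
    Returns (mapping table, interaction table, truth).
    """
    if not 0.0 <= stale_fraction <= 1.0:
        raise ValueError("stale_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(universe)
    n_stale = int(round(stale_fraction * n))
    stale_idx = set(rng.choice(n, size=n_stale, replace=False).tolist()) if n_stale else set()

    mapping_rows: list[tuple[str, str, str, str]] = []
    alias_of: dict[str, str] = {}
    for primary, symbol in cores:
        mapping_rows.append((symbol, primary, symbol, ""))
    for i, primary in enumerate(universe):
        num = primary[3:] if primary.startswith("SYN") else f"{i + 1:07d}"
        symbol = f"s{num}"
        secondary = f"ALT{num}"
        if i in stale_idx:
            submitted = f"OLD{num}"
            alias_of[primary] = submitted
        else:
            submitted = primary
        mapping_rows.append((submitted, primary, symbol, secondary))

    feedback: list[tuple[str, str]] = []
    leaves: list[tuple[str, str]] = []
    interaction_rows: list[tuple[str, str, str]] = []
    if interaction_spec is not None:
        members = list(interaction_spec.members)
        needed = 2 * interaction_spec.n_feedback_cycles + interaction_spec.n_leaf_edges
        if needed > len(members):
            raise ValueError("not enough network members for the planted interactions")
        picked = rng.choice(len(members), size=needed, replace=False).tolist()
        it = iter(picked)
        for _ in range(interaction_spec.n_feedback_cycles):
            a, b = members[next(it)], members[next(it)]
            feedback.append((a, b))
            interaction_rows.append((a, b, "genetic"))
            interaction_rows.append((b, a, "genetic"))
        for j in range(interaction_spec.n_leaf_edges):
            a = members[next(it)]
            outsider = f"EXT{j + 1:07d}"
            leaves.append((a, outsider))
            interaction_rows.append((a, outsider, "physical"))

    mapping = RawTable(
        ("submitted_id", "primary_identifier", "symbol", "secondary_identifier"),
        tuple(mapping_rows),
    )
    interactions = RawTable(("id_a", "id_b", "kind"), tuple(interaction_rows))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_table(mapping, os.path.join(out_dir, "mapping.csv"))
        write_table(interactions, os.path.join(out_dir, "interactions.csv"))
    return mapping, interactions, BackendTruth(alias_of, tuple(feedback), tuple(leaves))
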