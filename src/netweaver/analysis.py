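"""Post-build network analyses.

Covers the three operations applied to a merged network before statistics:

* duplicate-edge removal (one edge per source/target/interaction-type triple);
* the two-pass terminal-node filtration — keep nodes of degree >= 2, induce
  the subgraph, and repeat, which first strips terminal (degree-1) nodes and
  then the linker nodes that have become terminal themselves; run to fixpoint
  it eliminates every linear path and leaves only cycle-bearing structure;
* partitioning of targets by the exact set of core genes that regulate them
  (mono-, di-, tri-regulated blocks, etc.).

Degree is computed on the simple directed graph: parallel edges between the
same ordered pair (two interaction types) count once, so a 2-cycle gives each
endpoint total degree 2 and feedback loops survive filtration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx

from .network import Network
from .resolve import NodeRecord

__all__ = [
    "DegreeFilterConfig",
    "CoTargetPartition",
    "remove_duplicate_edges",
    "degree_filter",
    "co_target_partition",
    "network_counts",
]


@dataclass(frozen=True)
class DegreeFilterConfig:
    """Terminal-node filtration settings.

    ``min_degree`` is the keep threshold (default 2: degree-1 terminal nodes
    drop).  ``passes`` repeats the filter; ``fixpoint=True`` iterates until
    stable instead.  ``degree_mode`` is ``total`` (in+out, the default) or
    ``in_or_out`` (keep when either in-degree or out-degree alone meets the
    threshold).
    """

    min_degree: int = 2
    passes: int = 2
    fixpoint: bool = False
    degree_mode: Literal["total", "in_or_out"] = "total"

    def __post_init__(self) -> None:
        if self.min_degree < 1:
            raise ValueError("min_degree must be >= 1")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.degree_mode not in ("total", "in_or_out"):
            raise ValueError(f"unknown degree_mode {self.degree_mode!r}")


@dataclass(frozen=True)
class CoTargetPartition:
    """Disjoint blocks of target ids keyed by the exact set of regulating cores."""

    blocks: dict[frozenset[str], frozenset[str]]

    def block(self, *core_ids: str) -> frozenset[str]:
        return self.blocks.get(frozenset(core_ids), frozenset())

    @property
    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.blocks.values():
            out |= members
        return frozenset(out)


def remove_duplicate_edges(net: Network) -> Network:
    """Keep at most one edge per (source, target, interaction type)."""
    out = net.copy()
    seen: set[tuple[str, str, str]] = set()
    edges = []
    for e in out.edges:
        if e.key not in seen:
            seen.add(e.key)
            edges.append(e)
    out.edges = edges
    return out


def _simple_digraph(net: Network) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(
        (e.source.primary_identifier, e.target.primary_identifier) for e in net.edges
    )
    return g


def _keep_nodes(g: nx.DiGraph, cfg: DegreeFilterConfig) -> set[str]:
    if cfg.degree_mode == "total":
        return {n for n, d in g.degree() if d >= cfg.min_degree}
    return {
        n
        for n in g.nodes
        if g.in_degree(n) >= cfg.min_degree or g.out_degree(n) >= cfg.min_degree
    }


def _induce(net: Network, keep: set[str]) -> Network:
    out = Network(organism=net.organism)
    out.nodes = {pid: rec for pid, rec in net.nodes.items() if pid in keep}
    out.edges = [
        e
        for e in net.edges
        if e.source.primary_identifier in keep and e.target.primary_identifier in keep
    ]
    out.cores = [c for c in net.cores if c.primary_identifier in keep]
    return out


def degree_filter(net: Network, cfg: DegreeFilterConfig = DegreeFilterConfig()) -> Network:
    """Repeated terminal-node filtration.

    Each pass recomputes degrees on the current network, keeps nodes meeting
    the criterion, and induces the subgraph.  Core genes get no special
    protection — a core whose wheel collapses drops like any other node.
    Self-loops contribute 2 to total degree (networkx convention).
    """
    current = net
    previous_nodes: set[str] | None = None
    passes = 0
    while True:
        g = _simple_digraph(current)
        keep = _keep_nodes(g, cfg)
        current = _induce(current, keep)
        passes += 1
        if cfg.fixpoint:
            if previous_nodes == keep:
                break
            previous_nodes = keep
        elif passes >= cfg.passes:
            break
    return current


def co_target_partition(net: Network, cores: Sequence[NodeRecord] | None = None) -> CoTargetPartition:
    """Group non-core nodes by the exact set of cores with an edge onto them.

    A node targeted by cores {A} lands in the mono-regulated A block, one
    targeted by {A, B, C} in the tri-regulated block, and so on.  Nodes with
    no inbound core edge are excluded.  Blocks are disjoint and exhaustive
    over core-targeted nodes by construction.
    """
    if cores is None:
        cores = net.cores
    core_ids = {c.primary_identifier for c in cores}
    missing = core_ids - set(net.nodes)
    if missing:
        raise ValueError(f"cores not in network: {sorted(missing)}")
    regulators: dict[str, set[str]] = {}
    for e in net.edges:
        src = e.source.primary_identifier
        tgt = e.target.primary_identifier
        if src in core_ids and tgt not in core_ids:
            regulators.setdefault(tgt, set()).add(src)
    blocks: dict[frozenset[str], set[str]] = {}
    for tgt, regs in regulators.items():
        blocks.setdefault(frozenset(regs), set()).add(tgt)
    return CoTargetPartition({k: frozenset(v) for k, v in blocks.items()})


def network_counts(net: Network) -> dict:
    """Summary counts used as enrichment inputs.

    ``per_core_targets`` counts the distinct non-self nodes each core has an
    outgoing edge to — the "genes connected to each core gene".
    """
    per_core: dict[str, int] = {}
    for core in net.cores:
        cid = core.primary_identifier
        targets = {
            e.target.primary_identifier
            for e in net.edges
            if e.source.primary_identifier == cid
            and e.target.primary_identifier != cid
        }
        per_core[core.symbol or cid] = len(targets)
    return {
        "nodes": net.n_nodes,
        "edges": net.n_edges,
        "per_core_targets": per_core,
    }
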