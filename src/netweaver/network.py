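"""Wheel-network construction, merging and Cytoscape edge-table emission.

Each uploaded screen dataset becomes a *wheel*: its core gene at the hub with
one directed edge to every resolved target, labelled with the screen
technique (e.g. ``DamID``).  Wheels for the same organism merge by identifier
union, so targets shared between screens become the nodes that connect the
hubs.  Curated genetic/physical interactions from a resolver backend can then
be folded in, which adds outbound edges (and feedback loops) for existing
nodes and brings in new partner nodes.

The output is the seven-column edge CSV Cytoscape imports directly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .resolve import (
    INTERACTION_KINDS,
    InteractionRecord,
    NodeRecord,
    ResolverBackend,
    resolve_identifiers,
    validate_core_symbol,
)
from .tabular_io import RawTable

__all__ = [
    "Dataset",
    "EdgeRecord",
    "Network",
    "NETWORK_CSV_HEADER",
    "build_wheel",
    "merge_networks",
    "integrate_interactions",
    "write_network_csv",
    "read_network_csv",
]

logger = logging.getLogger("netweaver")

#: Cytoscape import header: "Source Symbol" is the source node column,
#: "Interaction Type" the interaction column, "Target Symbol" the target node.
NETWORK_CSV_HEADER = (
    "Source Symbol",
    "Source Primary Identifier",
    "Source Secondary Identifier",
    "Interaction Type",
    "Target Symbol",
    "Target Primary Identifier",
    "Target Secondary Identifier",
)


@dataclass(frozen=True)
class Dataset:
    """One uploaded screen: a named identifier list with its core gene.

    ``technique`` (e.g. ``"DamID"``, ``"RNAseq"``) becomes the interaction
    type of every core->target edge this dataset contributes.
    """

    name: str
    organism: str
    core_symbol: str
    technique: str
    identifiers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.technique:
            raise ValueError("technique label must be non-empty")
        if not self.name:
            raise ValueError("dataset name must be non-empty")


@dataclass(frozen=True)
class EdgeRecord:
    source: NodeRecord
    target: NodeRecord
    interaction_type: str
    dataset_name: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        """De-duplication key: (source primary, target primary, type)."""
        return (
            self.source.primary_identifier,
            self.target.primary_identifier,
            self.interaction_type,
        )


@dataclass
class Network:
    """Nodes keyed by primary identifier, a de-duplicated directed edge list,
    and the core genes of the wheels that built it."""

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: list[EdgeRecord] = field(default_factory=list)
    cores: list[NodeRecord] = field(default_factory=list)
    organism: str = ""

    def validate(self) -> None:
        for e in self.edges:
            if e.source.primary_identifier not in self.nodes:
                raise ValueError(f"edge source {e.source.primary_identifier} not a node")
            if e.target.primary_identifier not in self.nodes:
                raise ValueError(f"edge target {e.target.primary_identifier} not a node")
        for c in self.cores:
            if c.primary_identifier not in self.nodes:
                raise ValueError(f"core {c.primary_identifier} not a node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def copy(self) -> "Network":
        return Network(dict(self.nodes), list(self.edges), list(self.cores), self.organism)


def _add_node(net: Network, rec: NodeRecord) -> NodeRecord:
    existing = net.nodes.get(rec.primary_identifier)
    if existing is None:
        net.nodes[rec.primary_identifier] = rec
        return rec
    # keep the first record, but fill in fields the first lookup lacked
    if not existing.symbol and rec.symbol or not existing.secondary_identifier and rec.secondary_identifier:
        merged = NodeRecord(
            existing.primary_identifier,
            existing.symbol or rec.symbol,
            existing.secondary_identifier or rec.secondary_identifier,
            existing.organism or rec.organism,
        )
        net.nodes[rec.primary_identifier] = merged
        return merged
    return existing


def build_wheel(
    ds: Dataset,
    backend: ResolverBackend,
    passthrough_unresolved: bool = True,
    allow_self_loops: bool = False,
) -> Network:
    """Build the wheel network of one dataset: core at the hub, one directed
    ``core -> target`` edge per resolved target, labelled with the technique.

    A target that resolves to the core itself would be a self-loop; by default
    it is dropped with a warning.  Duplicate targets collapse to one edge.
    """
    core = validate_core_symbol(backend, ds.organism, ds.core_symbol)
    net = Network(organism=ds.organism)
    _add_node(net, core)
    net.cores.append(core)
    if ds.identifiers:
        targets, unresolved = resolve_identifiers(
            backend, ds.organism, ds.identifiers, passthrough_unresolved
        )
        if unresolved:
            logger.warning(
                "dataset %s: %d identifier(s) unresolved", ds.name, len(unresolved)
            )
        seen: set[tuple[str, str, str]] = set()
        for target in targets:
            if target.primary_identifier == core.primary_identifier and not allow_self_loops:
                logger.warning(
                    "dataset %s: core %s listed among its own targets; self-loop dropped",
                    ds.name,
                    core.symbol,
                )
                continue
            target = _add_node(net, target)
            edge = EdgeRecord(core, target, ds.technique, ds.name)
            if edge.key not in seen:
                seen.add(edge.key)
                net.edges.append(edge)
    return net


def merge_networks(wheels: Sequence[Network]) -> Network:
    """Union of wheel networks keyed by primary identifier.

    Shared targets become connector nodes between hubs.  Edges are
    de-duplicated on (source, target, interaction type); the same gene pair
    reported by two datasets under different techniques keeps both edges so
    provenance is never lost.  Row order is canonical — dataset registration
    order, then input row order — so the merge is order-independent up to
    that sort.
    """
    if not wheels:
        return Network()
    organisms = {w.organism for w in wheels}
    if len(organisms) > 1:
        raise ValueError(f"cannot merge networks across organisms: {sorted(organisms)}")
    merged = Network(organism=wheels[0].organism)
    seen_edges: set[tuple[str, str, str]] = set()
    seen_cores: set[str] = set()
    for wheel in wheels:
        for node in wheel.nodes.values():
            _add_node(merged, node)
        for core in wheel.cores:
            if core.primary_identifier not in seen_cores:
                seen_cores.add(core.primary_identifier)
                merged.cores.append(core)
        for edge in wheel.edges:
            if edge.key not in seen_edges:
                seen_edges.add(edge.key)
                merged.edges.append(edge)
    merged.validate()
    return merged


def integrate_interactions(
    net: Network, records: Iterable[InteractionRecord]
) -> Network:
    """Fold curated interactions into a network (monotone: only adds).

    Each record adds an edge ``query-gene -> partner`` typed ``genetic`` or
    ``physical``; partners not yet in the network are added as nodes.  This
    creates outbound edges for rim nodes and can close feedback loops onto a
    core.  Records for a different organism are rejected with a warning.
    """
    out = net.copy()
    seen = out.edge_keys()
    for rec in records:
        organisms = {rec.gene_a.organism, rec.gene_b.organism} - {""}
        if net.organism and organisms - {net.organism}:
            logger.warning(
                "interaction %s-%s rejected: organism mismatch %s",
                rec.gene_a.primary_identifier,
                rec.gene_b.primary_identifier,
                organisms,
            )
            continue
        source = _add_node(out, rec.gene_a)
        target = _add_node(out, rec.gene_b)
        edge = EdgeRecord(source, target, rec.interaction_kind, rec.provenance)
        if edge.key not in seen:
            seen.add(edge.key)
            out.edges.append(edge)
    out.validate()
    return out


def write_network_csv(net: Network, path: str) -> None:
    """Emit the Cytoscape-ready edge table: the seven-column header and one
    row per edge, in canonical (dataset, then input) order."""
    net.validate()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(NETWORK_CSV_HEADER)
        for e in net.edges:
            writer.writerow(
                (
                    e.source.symbol,
                    e.source.primary_identifier,
                    e.source.secondary_identifier,
                    e.interaction_type,
                    e.target.symbol,
                    e.target.primary_identifier,
                    e.target.secondary_identifier,
                )
            )


def read_network_csv(
    path: str, organism: str = "", cores: Sequence[str] = ()
) -> Network:
    """Rebuild a :class:`Network` from an emitted edge CSV.

    The edge table does not record which nodes were cores; pass their primary
    identifiers (or symbols) via ``cores``, or leave empty to infer them as
    the source nodes of non-curated (technique-labelled) edges.
    """
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        header = tuple(next(reader, ()))
        if header != NETWORK_CSV_HEADER:
            raise ValueError(f"{path}: not a network CSV (unexpected header {header})")
        rows = [row for row in reader if row]

    net = Network(organism=organism)
    inferred_cores: dict[str, NodeRecord] = {}
    for row in rows:
        s_sym, s_pri, s_sec, itype, t_sym, t_pri, t_sec = (row + [""] * 7)[:7]
        source = _add_node(net, NodeRecord(s_pri, s_sym, s_sec, organism))
        target = _add_node(net, NodeRecord(t_pri, t_sym, t_sec, organism))
        net.edges.append(EdgeRecord(source, target, itype))
        if itype not in INTERACTION_KINDS:
            inferred_cores.setdefault(source.primary_identifier, source)

    if cores:
        wanted = set(cores)
        net.cores = [
            n for n in net.nodes.values()
            if n.primary_identifier in wanted or n.symbol in wanted
        ]
        missing = wanted - {n.primary_identifier for n in net.cores} - {n.symbol for n in net.cores}
        if missing:
            raise ValueError(f"core(s) not found in network: {sorted(missing)}")
    else:
        net.cores = list(inferred_cores.values())
    net.validate()
    return net
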