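"""Node-attribute ingestion and the all-in-one attribute CSV (the AttR core).

Two attribute flavours exist:

* **List** attributes — a gene list sharing a property (a GO category, a
  reagent collection, ...); emitted as literal ``true``/``false`` per node so
  Cytoscape discrete mappings can key on them.
* **Valued** (discrete/continuous) attributes — identifier -> value columns
  such as RPKM expression levels; values pass through as text exactly as
  read, so nothing is reformatted between the source table and Cytoscape.

Identifiers in every attribute table are updated through the resolver before
mapping, so the emitted "Mapping Key" column carries the same primary
identifiers as the network CSV and Cytoscape joins the two on import.  Every
network node gets exactly one row, matched or not: unmatched nodes keep
empty/false cells and fall back to Cytoscape's default style.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .resolve import NodeRecord, ResolverBackend
from .tabular_io import RawTable

__all__ = [
    "ListAttribute",
    "ValuedAttribute",
    "AttributeBundle",
    "MAPPING_KEY_COLUMN",
    "load_valued_attributes",
    "load_list_attribute",
    "emit_attribute_csv",
    "read_attribute_csv",
]

logger = logging.getLogger("netweaver")

MAPPING_KEY_COLUMN = "Mapping Key"


@dataclass(frozen=True)
class ListAttribute:
    """A membership attribute: a user-typed label plus resolved member ids."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("list attribute name must be non-empty")


@dataclass(frozen=True)
class ValuedAttribute:
    """A discrete/continuous attribute: primary identifier -> text value."""

    name: str
    values: dict[str, str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("valued attribute name must be non-empty")


@dataclass
class AttributeBundle:
    """The attributes to emit, keyed onto a network's node list."""

    mapping_key_nodes: list[NodeRecord]
    attributes: list[ListAttribute | ValuedAttribute] = field(default_factory=list)

    def add(self, *attrs: ListAttribute | ValuedAttribute) -> "AttributeBundle":
        names = {a.name for a in self.attributes}
        for attr in attrs:
            if attr.name in names:
                raise ValueError(f"duplicate attribute name {attr.name!r}")
            names.add(attr.name)
            self.attributes.append(attr)
        return self


def _resolve_or_passthrough(
    backend: ResolverBackend, organism: str, identifier: str
) -> str:
    rec = backend.lookup_identifier(organism, identifier)
    return rec.primary_identifier if rec is not None else identifier


def load_valued_attributes(
    table: RawTable,
    mapping_col: int,
    value_cols: Sequence[tuple[int, str]],
    backend: ResolverBackend,
    organism: str,
) -> list[ValuedAttribute]:
    """Load one :class:`ValuedAttribute` per retained value column.

    ``value_cols`` names the columns to keep as ``(index, attribute name)``
    pairs; a column whose name the user cleared is simply not listed and is
    thereby excluded from processing.  Identifiers in the mapping column are
    updated through the resolver; a duplicated identifier keeps the last
    value seen, with a warning.
    """
    if not value_cols:
        raise ValueError("at least one value column must be named")
    names = [name for _, name in value_cols]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate value-column names: {names}")
    maps: dict[str, dict[str, str]] = {name: {} for name in names}
    n_resolved = 0
    for row in table.rows:
        submitted = row[mapping_col].strip()
        if not submitted:
            continue
        primary = _resolve_or_passthrough(backend, organism, submitted)
        n_resolved += 1
        for idx, name in value_cols:
            if primary in maps[name]:
                logger.warning(
                    "attribute %s: identifier %s duplicated; last value wins",
                    name,
                    primary,
                )
            maps[name][primary] = row[idx].strip()
    if n_resolved == 0:
        raise ValueError("mapping column contains no identifiers")
    return [ValuedAttribute(name, maps[name]) for name in names]


def load_list_attribute(
    table: RawTable,
    member_col: int,
    attr_name: str,
    backend: ResolverBackend,
    organism: str,
) -> ListAttribute:
    """Load a membership list from one column and give it the user's label.

    Members are resolved to primary identifiers; members absent from the
    network are retained here and simply stay unmatched at emission time.
    """
    if not attr_name:
        raise ValueError("list attribute name must be typed (non-empty)")
    members = {
        _resolve_or_passthrough(backend, organism, row[member_col].strip())
        for row in table.rows
        if row[member_col].strip()
    }
    return ListAttribute(attr_name, frozenset(members))


def emit_attribute_csv(bundle: AttributeBundle, path: str) -> None:
    """Write the all-in-one attribute table.

    First column is ``Mapping Key`` (the node primary identifier), then one
    column per attribute in load order.  List attributes emit ``true`` /
    ``false``; valued attributes emit the stored text or an empty cell.
    Exactly one row per network node.
    """
    header = [MAPPING_KEY_COLUMN] + [a.name for a in bundle.attributes]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for node in bundle.mapping_key_nodes:
            key = node.primary_identifier
            row = [key]
            for attr in bundle.attributes:
                if isinstance(attr, ListAttribute):
                    row.append("true" if key in attr.members else "false")
                else:
                    row.append(attr.values.get(key, ""))
            writer.writerow(row)


def read_attribute_csv(path: str) -> tuple[list[str], list[ValuedAttribute]]:
    """Read an emitted attribute CSV back as (mapping keys, value columns).

    Every column comes back as a :class:`ValuedAttribute` (list columns as
    their literal true/false strings), which is all round-trip checking and
    downstream enrichment need.
    """
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != MAPPING_KEY_COLUMN:
            raise ValueError(f"{path}: not an attribute CSV")
        keys: list[str] = []
        columns: dict[str, dict[str, str]] = {name: {} for name in header[1:]}
        for row in reader:
            if not row:
                continue
            key = row[0]
            keys.append(key)
            for name, cell in zip(header[1:], row[1:]):
                columns[name][key] = cell
    return keys, [ValuedAttribute(name, vals) for name, vals in columns.items()]
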