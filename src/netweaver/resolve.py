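"""Identifier resolution and interaction retrieval.

A pluggable resolver contract with two backends:

* :class:`LocalTableBackend` — a deterministic offline backend driven by two
  CSV tables: a mapping table ``submitted_id,primary_identifier,symbol,
  secondary_identifier`` and an interaction table ``id_a,id_b,kind``.
* :class:`InterMineBackend` — a thin client for an InterMine-family web
  service (e.g. FlyMine), used to validate a core gene symbol, update
  submitted identifiers to current primary identifiers, and pull curated
  genetic/physical interactions.

Resolution is deterministic for a fixed backend state, and unresolvable
identifiers are always reported, never silently dropped.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterable, Sequence

from .tabular_io import RawTable, read_table

__all__ = [
    "NodeRecord",
    "InteractionRecord",
    "ResolverBackend",
    "LocalTableBackend",
    "InterMineBackend",
    "ResolverError",
    "UnknownOrganismError",
    "UnknownSymbolError",
    "BackendUnavailableError",
    "INTERACTION_KINDS",
    "DEFAULT_MINE_REGISTRY",
    "validate_core_symbol",
    "resolve_identifiers",
    "fetch_interactions",
]

logger = logging.getLogger("netweaver")

#: The two curated interaction kinds retrievable from a resolver backend.
INTERACTION_KINDS = ("genetic", "physical")

#: Organism -> InterMine service endpoint. Editable: endpoints change over time.
DEFAULT_MINE_REGISTRY: dict[str, str] = {
    "Drosophila melanogaster": "https://www.flymine.org/flymine/service",
    "Homo sapiens": "https://www.humanmine.org/humanmine/service",
    "Mus musculus": "https://www.mousemine.org/mousemine/service",
    "Saccharomyces cerevisiae": "https://yeastmine.yeastgenome.org/yeastmine/service",
}


class ResolverError(RuntimeError):
    pass


class UnknownOrganismError(ResolverError):
    pass


class UnknownSymbolError(ResolverError):
    """The core gene symbol does not resolve; the session cannot proceed."""


class BackendUnavailableError(ResolverError):
    """The backend could not be reached; retriable, unlike a failed lookup."""


@dataclass(frozen=True)
class NodeRecord:
    """A resolved gene/protein: stable accession, symbol, alternate id, organism."""

    primary_identifier: str
    symbol: str
    secondary_identifier: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.primary_identifier:
            raise ValueError("primary_identifier must be non-empty")


@dataclass(frozen=True)
class InteractionRecord:
    """A curated pairwise interaction.

    ``gene_a`` is the query gene, so edge direction at network-emission time
    is query-gene -> partner; the pair itself is treated as unordered for
    de-duplication.
    """

    gene_a: NodeRecord
    gene_b: NodeRecord
    interaction_kind: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.interaction_kind not in INTERACTION_KINDS:
            raise ValueError(
                f"interaction_kind must be one of {INTERACTION_KINDS}, "
                f"got {self.interaction_kind!r}"
            )

    @property
    def unordered_key(self) -> tuple[frozenset[str], str]:
        return (
            frozenset((self.gene_a.primary_identifier, self.gene_b.primary_identifier)),
            self.interaction_kind,
        )


class ResolverBackend(ABC):
    """Contract every resolver backend fulfils."""

    @abstractmethod
    def organisms(self) -> list[str]:
        """Organisms this backend can serve."""

    @abstractmethod
    def lookup_symbol(self, organism: str, symbol: str) -> NodeRecord | None:
        """Resolve a gene symbol; exact match first, case-insensitive fallback."""

    @abstractmethod
    def lookup_identifier(self, organism: str, identifier: str) -> NodeRecord | None:
        """Update a submitted identifier to its current primary record."""

    @abstractmethod
    def interactions(
        self, organism: str, primary_ids: Sequence[str]
    ) -> list[InteractionRecord]:
        """All curated genetic/physical interactions involving the query ids."""

    def _check_organism(self, organism: str) -> None:
        if organism not in self.organisms():
            raise UnknownOrganismError(
                f"organism {organism!r} not in registry {self.organisms()}"
            )


class LocalTableBackend(ResolverBackend):
    """Deterministic offline backend over in-memory mapping/interaction tables.

    Parameters
    ----------
    organism:
        The single organism this table set describes.
    mapping:
        Rows ``(submitted_id, primary_identifier, symbol, secondary_identifier)``.
        A gene known under several submitted aliases appears once per alias.
    interactions:
        Rows ``(id_a, id_b, kind)`` with ids given as primary identifiers
        (submitted aliases are also accepted and updated on load).
    """

    def __init__(
        self,
        organism: str,
        mapping: Iterable[tuple[str, str, str, str]],
        interactions: Iterable[tuple[str, str, str]] = (),
    ) -> None:
        self.organism = organism
        self._by_submitted: dict[str, NodeRecord] = {}
        self._by_symbol: dict[str, NodeRecord] = {}
        self._by_symbol_ci: dict[str, NodeRecord] = {}
        for submitted, primary, symbol, secondary in mapping:
            rec = NodeRecord(primary, symbol, secondary, organism)
            self._by_submitted[submitted] = rec
            # primary ids and symbols resolve to themselves as well
            self._by_submitted.setdefault(primary, rec)
            self._by_symbol.setdefault(symbol, rec)
            self._by_symbol_ci.setdefault(symbol.lower(), rec)
        self._interactions: list[InteractionRecord] = []
        seen: set[tuple[frozenset[str], str]] = set()
        for id_a, id_b, kind in interactions:
            rec = InteractionRecord(
                self._node_or_bare(id_a), self._node_or_bare(id_b), kind, "local"
            )
            if rec.unordered_key not in seen:
                seen.add(rec.unordered_key)
                self._interactions.append(rec)

    @classmethod
    def from_csv(
        cls, organism: str, mapping_path: str, interactions_path: str | None = None
    ) -> "LocalTableBackend":
        def body(table: RawTable, width: int) -> list[tuple[str, ...]]:
            return [tuple(c.strip() for c in row[:width]) for row in table.rows]

        mapping = body(read_table(mapping_path, has_header=True), 4)
        inter: list[tuple[str, ...]] = []
        if interactions_path is not None:
            inter = body(read_table(interactions_path, has_header=True), 3)
        return cls(organism, mapping, inter)  # type: ignore[arg-type]

    def _node_or_bare(self, identifier: str) -> NodeRecord:
        rec = self._by_submitted.get(identifier)
        return rec if rec is not None else NodeRecord(identifier, identifier, "", self.organism)

    def organisms(self) -> list[str]:
        return [self.organism]

    def lookup_symbol(self, organism: str, symbol: str) -> NodeRecord | None:
        self._check_organism(organism)
        rec = self._by_symbol.get(symbol)
        if rec is not None:
            return rec
        rec = self._by_symbol_ci.get(symbol.lower())
        if rec is not None:
            logger.warning(
                "symbol %r matched %r only case-insensitively", symbol, rec.symbol
            )
        return rec

    def lookup_identifier(self, organism: str, identifier: str) -> NodeRecord | None:
        self._check_organism(organism)
        return self._by_submitted.get(identifier)

    def interactions(
        self, organism: str, primary_ids: Sequence[str]
    ) -> list[InteractionRecord]:
        self._check_organism(organism)
        wanted = set(primary_ids)
        out: list[InteractionRecord] = []
        for rec in self._interactions:
            if rec.gene_a.primary_identifier in wanted:
                out.append(rec)
            elif rec.gene_b.primary_identifier in wanted:
                # orient the edge query-gene -> partner
                out.append(
                    InteractionRecord(rec.gene_b, rec.gene_a, rec.interaction_kind, rec.provenance)
                )
        return out


class InterMineBackend(ResolverBackend):
    """Live backend over the InterMine JSON web-service API.

    Queries are batched and retried once on transient failure.  Needs network
    access; the offline :class:`LocalTableBackend` is the reproducible path.
    """

    def __init__(
        self,
        registry: dict[str, str] | None = None,
        batch_size: int = 100,
        timeout: float = 30.0,
    ) -> None:
        self.registry = dict(DEFAULT_MINE_REGISTRY if registry is None else registry)
        self.batch_size = batch_size
        self.timeout = timeout

    def organisms(self) -> list[str]:
        return list(self.registry)

    # -- web-service plumbing -------------------------------------------------

    def _query(self, organism: str, xml: str) -> list[list]:
        base = self.registry[organism]
        url = f"{base}/query/results?" + urllib.parse.urlencode(
            {"query": xml, "format": "json"}
        )
        last_err: Exception | None = None
        for attempt in range(2):  # retry once
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return json.load(resp).get("results", [])
            except Exception as err:  # pragma: no cover - network only
                last_err = err
                if attempt == 0:
                    time.sleep(1.0)
        raise BackendUnavailableError(f"InterMine service unreachable: {last_err}")

    @staticmethod
    def _gene_query(constraint: str) -> str:
        return (
            '<query model="genomic" view="Gene.primaryIdentifier Gene.symbol '
            'Gene.secondaryIdentifier" constraintLogic="A">'
            f"{constraint}</query>"
        )

    def lookup_symbol(self, organism: str, symbol: str) -> NodeRecord | None:
        self._check_organism(organism)
        xml = self._gene_query(
            f'<constraint path="Gene" op="LOOKUP" value="{symbol}" code="A"/>'
        )
        rows = self._query(organism, xml)
        if not rows:
            return None
        primary, sym, secondary = (rows[0] + ["", "", ""])[:3]
        return NodeRecord(str(primary), str(sym or symbol), str(secondary or ""), organism)

    def lookup_identifier(self, organism: str, identifier: str) -> NodeRecord | None:
        return self.lookup_symbol(organism, identifier)

    def interactions(
        self, organism: str, primary_ids: Sequence[str]
    ) -> list[InteractionRecord]:
        self._check_organism(organism)
        out: list[InteractionRecord] = []
        for start in range(0, len(primary_ids), self.batch_size):
            batch = primary_ids[start : start + self.batch_size]
            values = "|".join(batch)
            xml = (
                '<query model="genomic" view="Gene.primaryIdentifier Gene.symbol '
                "Gene.interactions.participant2.primaryIdentifier "
                "Gene.interactions.participant2.symbol "
                'Gene.interactions.details.relationshipType" constraintLogic="A">'
                f'<constraint path="Gene.primaryIdentifier" op="ONE OF" code="A">'
                + "".join(f"<value>{v}</value>" for v in batch)
                + "</constraint></query>"
            )
            del values
            for row in self._query(organism, xml):
                a_id, a_sym, b_id, b_sym, kind = (list(row) + [""] * 5)[:5]
                kind = str(kind).lower()
                if kind not in INTERACTION_KINDS:
                    continue
                out.append(
                    InteractionRecord(
                        NodeRecord(str(a_id), str(a_sym or a_id), "", organism),
                        NodeRecord(str(b_id), str(b_sym or b_id), "", organism),
                        kind,
                        "intermine",
                    )
                )
        return out


# -- resolver operations ------------------------------------------------------


def validate_core_symbol(
    backend: ResolverBackend, organism: str, symbol: str
) -> NodeRecord:
    """Resolve the core gene symbol; a misspelled symbol is fatal."""
    rec = backend.lookup_symbol(organism, symbol)
    if rec is None:
        raise UnknownSymbolError(
            f"core gene symbol {symbol!r} is unknown for {organism}; "
            "check the spelling"
        )
    return rec


def resolve_identifiers(
    backend: ResolverBackend,
    organism: str,
    ids: Sequence[str],
    passthrough_unresolved: bool = True,
) -> tuple[list[NodeRecord], list[str]]:
    """Update submitted identifiers to current primary records.

    Returns ``(records, unresolved)``.  Inputs are de-duplicated keeping the
    first occurrence (on the resolved primary identifier, so two aliases of
    one gene yield one record).  Unresolved inputs are reported in
    ``unresolved``; with ``passthrough_unresolved`` they additionally appear
    in ``records`` as bare pass-through nodes (primary = submitted text),
    which keeps network sizes stable.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    records: list[NodeRecord] = []
    unresolved: list[str] = []
    seen_primary: set[str] = set()
    seen_input: set[str] = set()
    for submitted in ids:
        submitted = submitted.strip()
        if not submitted or submitted in seen_input:
            continue
        seen_input.add(submitted)
        rec = backend.lookup_identifier(organism, submitted)
        if rec is None:
            unresolved.append(submitted)
            if not passthrough_unresolved:
                continue
            rec = NodeRecord(submitted, submitted, "", organism)
            logger.warning("identifier %r unresolved; passing through as-is", submitted)
        if rec.primary_identifier not in seen_primary:
            seen_primary.add(rec.primary_identifier)
            records.append(rec)
    return records, unresolved


def fetch_interactions(
    backend: ResolverBackend, organism: str, nodes: Sequence[NodeRecord]
) -> list[InteractionRecord]:
    """All curated genetic/physical interactions involving the given nodes,
    de-duplicated per (unordered gene pair, kind)."""
    ids = [n.primary_identifier for n in nodes]
    seen: set[tuple[frozenset[str], str]] = set()
    out: list[InteractionRecord] = []
    for rec in backend.interactions(organism, ids):
        if rec.unordered_key not in seen:
            seen.add(rec.unordered_key)
            out.append(rec)
    return out
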