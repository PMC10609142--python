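"""Offline taxID -> canonical-rank lineage resolution from NCBI taxdump files.

Reads the flat-file taxonomy distribution (``nodes.dmp``, ``names.dmp``,
optional ``merged.dmp``; fields separated by ``\\t|\\t``, lines terminated
``\\t|``) into an in-memory database supporting O(depth) parent walks, and
fills the seven canonical lineage slots (superkingdom..species) by walking
parent pointers to the root.  Ranks outside the canonical span (strain,
"no rank", clade, ...) are skipped; unfilled slots carry the visible
sentinel ``"unclassified"`` so downstream distribution tables have an
explicit bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path

from .errors import TaxdumpError, UnknownTaxIdError

#: The seven-rank span used for lineage slots and distribution tables.
CANONICAL_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Sentinel for a lineage slot no ancestor resolves.
UNCLASSIFIED = "unclassified"

# Newer NCBI dumps renamed the top rank "superkingdom" to "domain";
# both fill the same slot.
_RANK_ALIASES = {"domain": "superkingdom"}

_RANK_TO_FIELD = {
    "superkingdom": "superkingdom",
    "phylum": "phylum",
    "class": "class_",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
}


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str


@dataclass(frozen=True)
class Lineage:
    """The seven canonical ranks resolved for one taxid."""

    superkingdom: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED
    species: str = UNCLASSIFIED

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


class TaxDB:
    """In-memory taxonomy: nodes keyed by taxid plus an old->new merged map."""

    def __init__(self, nodes: dict[int, TaxNode], merged: dict[int, int] | None = None):
        self.nodes = nodes
        self.merged = merged or {}
        self._lineage_cache: dict[int, Lineage] = {}
        self._validate()

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or self.merged.get(taxid) in self.nodes

    def canonical_taxid(self, taxid: int) -> int:
        if taxid in self.nodes:
            return taxid
        if taxid in self.merged and self.merged[taxid] in self.nodes:
            return self.merged[taxid]
        raise UnknownTaxIdError(taxid)

    def _validate(self) -> None:
        # Dangling parents.
        for node in self.nodes.values():
            if node.parent_taxid != node.taxid and node.parent_taxid not in self.nodes:
                raise TaxdumpError(
                    f"taxid {node.taxid} references absent parent {node.parent_taxid}"
                )
        # Cycle detection: walk each node to a root, marking finished nodes.
        finished: set[int] = set()
        for start in self.nodes:
            path: list[int] = []
            on_path: set[int] = set()
            tid = start
            while tid not in finished:
                if tid in on_path:
                    raise TaxdumpError(f"cycle detected in taxonomy involving taxid {tid}")
                on_path.add(tid)
                path.append(tid)
                node = self.nodes[tid]
                if node.parent_taxid == tid:  # root
                    break
                tid = node.parent_taxid
            finished.update(path)


def _dmp_fields(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\t|").split("\t|\t")


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxDB:
    """Load a taxdump into a validated :class:`TaxDB`.

    Only the "scientific name" class is read from the names file; a node
    without one gets an empty name.  Validation aborts on a dangling
    parent or a parent-pointer cycle.
    """
    names: dict[int, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for line in fh:
            parts = _dmp_fields(line)
            if len(parts) < 4:
                raise TaxdumpError(f"malformed names line: {line!r}")
            if parts[3].strip() == "scientific name":
                names[int(parts[0])] = parts[1].strip()

    nodes: dict[int, TaxNode] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for line in fh:
            parts = _dmp_fields(line)
            if len(parts) < 3:
                raise TaxdumpError(f"malformed nodes line: {line!r}")
            taxid = int(parts[0])
            nodes[taxid] = TaxNode(
                taxid=taxid,
                parent_taxid=int(parts[1]),
                rank=parts[2].strip().lower(),
                scientific_name=names.get(taxid, ""),
            )

    merged: dict[int, int] = {}
    if merged_path is not None:
        with open(merged_path, encoding="utf-8") as fh:
            for line in fh:
                parts = _dmp_fields(line)
                if len(parts) < 2:
                    raise TaxdumpError(f"malformed merged line: {line!r}")
                merged[int(parts[0])] = int(parts[1])

    return TaxDB(nodes, merged)


def resolve_lineage(db: TaxDB, taxid: int) -> Lineage:
    """Resolve the seven canonical ranks for ``taxid`` by a parent walk.

    Deterministic and memoised per database; raises
    :class:`~prokmeta.errors.UnknownTaxIdError` for a taxid absent from the
    database (after consulting the merged-ID map).
    """
    tid = db.canonical_taxid(taxid)
    cached = db._lineage_cache.get(tid)
    if cached is not None:
        return cached
    slots: dict[str, str] = {}
    cur = tid
    while True:
        node = db.nodes[cur]
        rank = _RANK_ALIASES.get(node.rank, node.rank)
        if rank in _RANK_TO_FIELD and node.scientific_name:
            slots.setdefault(_RANK_TO_FIELD[rank], node.scientific_name)
        if node.parent_taxid == cur:
            break
        cur = node.parent_taxid
    lineage = Lineage(**slots)
    db._lineage_cache[tid] = lineage
    return lineage
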