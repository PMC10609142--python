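"""Parse the raw ``Replicons`` field and count chromosomes and plasmids.

The source metadata lists every replicon of an assembly in one
``;``-separated text cell, each entry optionally shaped
``descriptor:acc1/acc2``.  Classification is by descriptor: anything
containing the word "plasmid" (catches "megaplasmid", "plasmid pXO1") is a
plasmid; otherwise a descriptor starting with "chromosome" (catches
"chromosome 2", "chromosome II") is a chromosome; everything else is
``other`` and logged, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

KIND_CHROMOSOME = "chromosome"
KIND_PLASMID = "plasmid"
KIND_OTHER = "other"


@dataclass(frozen=True)
class RepliconEntry:
    kind: str
    label: str
    accessions: tuple[str, ...]


@dataclass(frozen=True)
class RepliconSet:
    """Classified replicon entries with per-kind counts.

    Counts are derived from ``entries``, so the conservation invariant
    n_chromosomes + n_plasmids + n_other == len(entries) holds by
    construction; empty/missing input yields all-zero counts.
    """

    entries: tuple[RepliconEntry, ...] = ()

    @property
    def n_chromosomes(self) -> int:
        return sum(1 for e in self.entries if e.kind == KIND_CHROMOSOME)

    @property
    def n_plasmids(self) -> int:
        return sum(1 for e in self.entries if e.kind == KIND_PLASMID)

    @property
    def n_other(self) -> int:
        return sum(1 for e in self.entries if e.kind == KIND_OTHER)

    def to_string(self) -> str:
        """Canonical re-serialization; parsing it reproduces the counts."""
        parts = []
        for e in self.entries:
            if e.accessions:
                parts.append(f"{e.label}:{'/'.join(e.accessions)}")
            else:
                parts.append(e.label)
        return "; ".join(parts)


def _classify(descriptor: str) -> str:
    d = descriptor.lower()
    if "plasmid" in d:
        return KIND_PLASMID
    if d.startswith("chromosome"):
        return KIND_CHROMOSOME
    return KIND_OTHER


def parse_replicons(raw: str | None) -> RepliconSet:
    """Total function: any text (or None / the ``-`` sentinel) parses.

    Entries are split on ``;``; whitespace around ``;`` and ``:`` is
    stripped and empty entries between separators are ignored.  Entries
    with no ``:`` are classified by their bare descriptor.
    """
    if raw is None or not raw.strip() or raw.strip() == "-":
        return RepliconSet()
    entries = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        label, _, acc = chunk.partition(":")
        label = label.strip()
        accessions = tuple(a.strip() for a in acc.split("/") if a.strip()) if acc else ()
        kind = _classify(label)
        if kind == KIND_OTHER:
            logger.debug("unclassifiable replicon descriptor %r -> other", label)
        entries.append(RepliconEntry(kind=kind, label=label, accessions=accessions))
    return RepliconSet(entries=tuple(entries))


def is_multichromosomal(rs: RepliconSet) -> bool:
    """A multipartite genome carries two or more chromosomes."""
    return rs.n_chromosomes >= 2


def has_plasmid(rs: RepliconSet) -> bool:
    """A plasmid-bearing genome carries at least one plasmid replicon."""
    return rs.n_plasmids >= 1
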