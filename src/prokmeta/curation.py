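"""Assemble the curated complete-genome metadata table.

Curation keeps exactly the rows whose assembly level is "Complete Genome"
(whitespace-trimmed, case-insensitive), attaches chromosome/plasmid counts
parsed from the replicon field, and resolves the seven-rank lineage from
the taxid.  Records whose taxid the taxonomy database cannot resolve are
retained with an all-unclassified lineage and logged, so genome counts
stay stable relative to the source file.  Genome size stays in Mb as
published.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

from .errors import UnknownTaxIdError
from .metadata_io import RawGenomeRecord
from .replicon import parse_replicons
from .taxonomy import Lineage, TaxDB, resolve_lineage

logger = logging.getLogger(__name__)

#: Assembly-level selector for a complete genome (compared case-insensitively).
COMPLETE_STATUS = "complete genome"


@dataclass
class CuratedRecord:
    """One row of the curated metadata table: genomic features + replicon
    counts + taxonomy + provenance."""

    organism_name: str
    taxid: int
    size_mb: float | None
    gc_percent: float | None
    replicons_raw: str | None
    n_chromosomes: int
    n_plasmids: int
    genes: int | None
    proteins: int | None
    release_date: _dt.date | None
    ftp_path: str | None
    superkingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str


@dataclass
class CurationLog:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_status: int = 0
    taxonomy_misses: list[int] = field(default_factory=list)


def is_complete(status: str) -> bool:
    return status.strip().casefold() == COMPLETE_STATUS


def curate(raw: list[RawGenomeRecord], db: TaxDB) -> tuple[list[CuratedRecord], CurationLog]:
    """Filter to complete genomes and attach replicon counts + lineage.

    Total: problems are logged, never raised.  Source order is preserved.
    """
    log = CurationLog(n_input=len(raw))
    curated: list[CuratedRecord] = []
    for rec in raw:
        if not is_complete(rec.status):
            log.n_dropped_status += 1
            continue
        rs = parse_replicons(rec.replicons)
        try:
            lineage = resolve_lineage(db, rec.taxid)
        except UnknownTaxIdError:
            log.taxonomy_misses.append(rec.taxid)
            lineage = Lineage()
        curated.append(
            CuratedRecord(
                organism_name=rec.organism_name,
                taxid=rec.taxid,
                size_mb=rec.size_mb,
                gc_percent=rec.gc_percent,
                replicons_raw=rec.replicons,
                n_chromosomes=rs.n_chromosomes,
                n_plasmids=rs.n_plasmids,
                genes=rec.genes,
                proteins=rec.proteins,
                release_date=rec.release_date,
                ftp_path=rec.ftp_path,
                superkingdom=lineage.superkingdom,
                phylum=lineage.phylum,
                class_=lineage.class_,
                order=lineage.order,
                family=lineage.family,
                genus=lineage.genus,
                species=lineage.species,
            )
        )
    log.n_kept = len(curated)
    if log.taxonomy_misses:
        logger.warning(
            "%d record(s) kept with unresolvable taxid(s): %s",
            len(log.taxonomy_misses),
            log.taxonomy_misses[:10],
        )
    return curated, log
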