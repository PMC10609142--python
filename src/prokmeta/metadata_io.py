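"""Read/write the NCBI genome-report dialect and the curated CSV product.

The genome report is a UTF-8 tab-delimited table whose first line is a
header beginning with ``#``.  Columns are identified by header *name*,
never by position, so column permutations are harmless.  The missing-value
sentinel is ``-`` (an empty cell is treated the same way).

Two parsing modes exist:

* lenient (default): parsing is total — malformed numeric cells become
  missing, rows without a usable organism name / taxid / status are
  rejected, and every coercion or rejection is logged with its line number;
* strict: the first malformed cell or missing mandatory column aborts with
  a :class:`~prokmeta.errors.ReportParseError` naming the line.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import tempfile
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .errors import FetchError, InputError, ReportParseError, SchemaError

logger = logging.getLogger(__name__)

#: Missing-value sentinel used by the genome-report dialect.
MISSING_SENTINEL = "-"

#: Default remote location of the prokaryote genome report.
DEFAULT_REPORT_URL = "https://ftp.ncbi.nlm.nih.gov/genomes/GENOME_REPORTS/prokaryotes.txt"

# Header-name -> record-field mapping (lowercased, leading '#' stripped).
# Kept in one table so a dialect drift is a one-line fix.
_COLUMN_MAP = {
    "organism/name": "organism_name",
    "organism name": "organism_name",
    "taxid": "taxid",
    "size (mb)": "size_mb",
    "gc%": "gc_percent",
    "replicons": "replicons",
    "genes": "genes",
    "proteins": "proteins",
    "release date": "release_date",
    "status": "status",
    "ftp path": "ftp_path",
}

_MANDATORY_FIELDS = ("organism_name", "taxid", "status")

_DATE_FORMATS = ("%Y/%m/%d", "%Y-%m-%d")


@dataclass
class RawGenomeRecord:
    """One parsed row of the genome report.

    ``extra`` preserves every source column not mapped to a typed field
    (BioProject, Group, SubGroup, Center, Assembly Accession, Strain, ...).
    """

    organism_name: str
    taxid: int
    status: str
    size_mb: float | None = None
    gc_percent: float | None = None
    replicons: str | None = None
    genes: int | None = None
    proteins: int | None = None
    release_date: _dt.date | None = None
    ftp_path: str | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class ParseEvent:
    line_no: int
    field: str
    reason: str
    action: str  # "coerced" | "rejected"


@dataclass
class ParseLog:
    """Audit trail of every coercion and rejection during a parse."""

    events: list[ParseEvent] = field(default_factory=list)

    def add(self, line_no: int, field_name: str, reason: str, action: str) -> None:
        self.events.append(ParseEvent(line_no, field_name, reason, action))

    @property
    def n_coerced(self) -> int:
        return sum(1 for e in self.events if e.action == "coerced")

    @property
    def n_rejected(self) -> int:
        return sum(1 for e in self.events if e.action == "rejected")


def _is_missing(cell: str) -> bool:
    cell = cell.strip()
    return cell == "" or cell == MISSING_SENTINEL


def _parse_date(cell: str) -> _dt.date | None:
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(cell.strip(), fmt).date()
        except ValueError:
            continue
    return None


def _open_source(source) -> tuple[Iterable[str], bool]:
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    try:
        handle = path.open("r", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read genome report {path}: {exc}") from exc
    return handle, True


def read_genome_report(
    source: str | Path | IO[str], strict: bool = False
) -> tuple[list[RawGenomeRecord], ParseLog]:
    """Parse a genome report into records plus an audit log.

    Parameters
    ----------
    source
        Path to, or open text stream of, a tab-delimited report whose first
        line is a ``#``-prefixed header.
    strict
        Abort on the first malformed numeric cell or missing mandatory
        column instead of coercing/rejecting leniently.
    """
    stream, owned = _open_source(source)
    try:
        return _parse_stream(stream, strict)
    finally:
        if owned:
            stream.close()


def _parse_stream(stream: Iterable[str], strict: bool) -> tuple[list[RawGenomeRecord], ParseLog]:
    log = ParseLog()
    records: list[RawGenomeRecord] = []
    it = iter(stream)
    try:
        header_line = next(it)
    except StopIteration:
        if strict:
            raise ReportParseError("genome report is empty: no header line", line_no=1)
        log.add(1, "<header>", "empty input: no header line", "rejected")
        return records, log
    if not header_line.startswith("#"):
        if strict:
            raise ReportParseError("header line must begin with '#'", line_no=1)
        log.add(1, "<header>", "header line does not begin with '#'", "coerced")
    header = [h.strip() for h in header_line.lstrip("#").rstrip("\n").split("\t")]
    fields = [_COLUMN_MAP.get(h.lower()) for h in header]
    present = {f for f in fields if f}
    missing_mandatory = [m for m in _MANDATORY_FIELDS if m not in present]
    if missing_mandatory:
        reason = f"mandatory column(s) missing from header: {', '.join(missing_mandatory)}"
        if strict:
            raise ReportParseError(reason, line_no=1)
        log.add(1, "<header>", reason, "rejected")
        return records, log

    for line_no, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            if strict:
                raise ReportParseError(
                    f"expected {len(header)} cells, got {len(cells)}", line_no=line_no
                )
            log.add(line_no, "<row>", f"cell count {len(cells)} != header {len(header)}", "coerced")
            cells = (cells + [""] * len(header))[: len(header)]
        rec = _parse_row(header, fields, cells, line_no, strict, log)
        if rec is not None:
            records.append(rec)
    return records, log


def _parse_row(header, fields, cells, line_no, strict, log) -> RawGenomeRecord | None:
    values: dict[str, object] = {}
    extra: dict[str, str] = {}
    for name, fld, cell in zip(header, fields, cells):
        if fld is None:
            extra[name] = cell.strip()
            continue
        values[fld] = cell

    def bad(field_name: str, reason: str) -> None:
        if strict:
            raise ReportParseError(f"{field_name}: {reason}", line_no=line_no)
        log.add(line_no, field_name, reason, "coerced")

    organism = str(values.get("organism_name", "")).strip()
    status = str(values.get("status", "")).strip()
    taxid_cell = str(values.get("taxid", "")).strip()
    taxid: int | None = None
    if not _is_missing(taxid_cell):
        try:
            taxid = int(taxid_cell)
            if taxid <= 0:
                taxid = None
        except ValueError:
            taxid = None
    if not organism or _is_missing(organism) or taxid is None or not status or _is_missing(status):
        reason = "missing/invalid mandatory field (organism, taxid or status)"
        if strict:
            raise ReportParseError(reason, line_no=line_no)
        log.add(line_no, "<row>", reason, "rejected")
        return None

    def num(field_name: str, caster, lo=None, hi=None, lo_open=False):
        cell = str(values.get(field_name, "")).strip()
        if _is_missing(cell):
            return None
        try:
            v = caster(cell)
        except ValueError:
            bad(field_name, f"unparseable value {cell!r}")
            return None
        if lo is not None and (v <= lo if lo_open else v < lo):
            bad(field_name, f"value {v} out of range")
            return None
        if hi is not None and v > hi:
            bad(field_name, f"value {v} out of range")
            return None
        return v

    size_mb = num("size_mb", float, lo=0, lo_open=True)
    gc = num("gc_percent", float, lo=0, hi=100, lo_open=True)
    genes = num("genes", int, lo=0)
    proteins = num("proteins", int, lo=0)

    date_cell = str(values.get("release_date", "")).strip()
    release_date = None
    if not _is_missing(date_cell):
        release_date = _parse_date(date_cell)
        if release_date is None:
            bad("release_date", f"unparseable date {date_cell!r}")

    repl = str(values.get("replicons", "")).strip()
    ftp = str(values.get("ftp_path", "")).strip()
    return RawGenomeRecord(
        organism_name=organism,
        taxid=taxid,
        status=status,
        size_mb=size_mb,
        gc_percent=gc,
        replicons=None if _is_missing(repl) else repl,
        genes=genes,
        proteins=proteins,
        release_date=release_date,
        ftp_path=None if _is_missing(ftp) else ftp,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Curated CSV
# ---------------------------------------------------------------------------

#: Fixed column order of the curated CSV (the downloadable metadata table).
CURATED_COLUMNS = [
    "organism_name",
    "taxid",
    "size_mb",
    "gc_percent",
    "replicons",
    "n_chromosomes",
    "n_plasmids",
    "genes",
    "proteins",
    "release_date",
    "ftp_path",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
]

_INT_CURATED = ("taxid", "n_chromosomes", "n_plasmids", "genes", "proteins")
_FLOAT_CURATED = ("size_mb", "gc_percent")


def write_curated_csv(records, dest: str | Path) -> None:
    """Write curated records as an RFC-4180-style CSV with a fixed header.

    Missing values become empty cells; a header row is always written,
    even for zero records.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "organism_name": rec.organism_name,
                "taxid": rec.taxid,
                "size_mb": rec.size_mb,
                "gc_percent": rec.gc_percent,
                "replicons": rec.replicons_raw,
                "n_chromosomes": rec.n_chromosomes,
                "n_plasmids": rec.n_plasmids,
                "genes": rec.genes,
                "proteins": rec.proteins,
                "release_date": rec.release_date.isoformat() if rec.release_date else None,
                "ftp_path": rec.ftp_path,
                "superkingdom": rec.superkingdom,
                "phylum": rec.phylum,
                "class": rec.class_,
                "order": rec.order,
                "family": rec.family,
                "genus": rec.genus,
                "species": rec.species,
            }
        )
    df = pd.DataFrame(rows, columns=CURATED_COLUMNS)
    for col in ("genes", "proteins"):
        df[col] = df[col].astype("Int64")
    try:
        df.to_csv(dest, index=False, na_rep="")
    except OSError as exc:
        raise InputError(f"cannot write curated CSV to {dest}: {exc}") from exc


def read_curated_csv(path: str | Path):
    """Inverse of :func:`write_curated_csv`; errors on schema mismatch."""
    from .curation import CuratedRecord  # deferred: avoids an import cycle

    try:
        df = pd.read_csv(
            path,
            dtype={c: "string" for c in CURATED_COLUMNS},
            keep_default_na=False,
            na_values=[""],
        )
    except OSError as exc:
        raise InputError(f"cannot read curated CSV {path}: {exc}") from exc
    if list(df.columns) != CURATED_COLUMNS:
        raise SchemaError(
            f"curated CSV schema mismatch: expected {CURATED_COLUMNS}, got {list(df.columns)}"
        )

    def opt(v, caster):
        if v is pd.NA or v is None:
            return None
        return caster(v)

    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(CURATED_COLUMNS, row))
        records.append(
            CuratedRecord(
                organism_name=str(d["organism_name"]),
                taxid=int(d["taxid"]),
                size_mb=opt(d["size_mb"], float),
                gc_percent=opt(d["gc_percent"], float),
                replicons_raw=opt(d["replicons"], str),
                n_chromosomes=int(d["n_chromosomes"]),
                n_plasmids=int(d["n_plasmids"]),
                genes=opt(d["genes"], int),
                proteins=opt(d["proteins"], int),
                release_date=opt(d["release_date"], _dt.date.fromisoformat),
                ftp_path=opt(d["ftp_path"], str),
                superkingdom=str(d["superkingdom"]),
                phylum=str(d["phylum"]),
                class_=str(d["class"]),
                order=str(d["order"]),
                family=str(d["family"]),
                genus=str(d["genus"]),
                species=str(d["species"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Remote fetch with cache
# ---------------------------------------------------------------------------


def fetch_report(
    url: str = DEFAULT_REPORT_URL,
    cache_dir: str | Path = "~/.cache/prokmeta",
    max_age: float = 24 * 3600,
) -> Path:
    """Return a local copy of the report, at most ``max_age`` seconds old.

    A fresh-enough cached copy is returned without touching the network.
    Otherwise the URL is downloaded atomically (temp file + rename).  On
    network failure a stale cache is returned with a warning; with no cache
    at all, :class:`~prokmeta.errors.FetchError` is raised.
    """
    cache_dir = Path(cache_dir).expanduser()
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_path = cache_dir / (Path(url.rstrip("/")).name or "report.txt")

    if cache_path.exists():
        age = time.time() - cache_path.stat().st_mtime
        if age <= max_age:
            logger.info("using cached report %s (age %.0f s)", cache_path, age)
            return cache_path

    try:
        fd, tmp = tempfile.mkstemp(dir=cache_dir, suffix=".part")
        try:
            with urllib.request.urlopen(url) as resp, os.fdopen(fd, "wb") as out:
                while chunk := resp.read(1 << 20):
                    out.write(chunk)
            os.replace(tmp, cache_path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)
        logger.info("downloaded fresh report from %s", url)
        return cache_path
    except (urllib.error.URLError, OSError) as exc:
        if cache_path.exists():
            logger.warning("download failed (%s); returning stale cache %s", exc, cache_path)
            return cache_path
        raise FetchError(f"cannot fetch {url} and no cached copy exists: {exc}") from exc
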