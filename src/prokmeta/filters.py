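"""Declarative, composable filtering of curated records.

A :class:`FilterSpec` is the conjunction of at most one taxonomic-rank
selection and inclusive numeric ranges over the six genomic features.
Records missing a value for a filtered numeric feature are excluded by
that clause (so prevalence denominators match what a user sees in the
filtered table); the exclusion count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as _dc_fields

from .curation import CuratedRecord
from .errors import FilterSpecError
from .taxonomy import CANONICAL_RANKS

logger = logging.getLogger(__name__)

Range = tuple[float | None, float | None]

_RANGE_ATTR = {
    "size_range": "size_mb",
    "gc_range": "gc_percent",
    "chromosome_range": "n_chromosomes",
    "plasmid_range": "n_plasmids",
    "gene_range": "genes",
    "protein_range": "proteins",
}

_RANK_ATTR = {r: ("class_" if r == "class" else r) for r in CANONICAL_RANKS}


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of one optional rank selection and inclusive ranges.

    Each range is ``(lo, hi)`` with ``None`` for an open end; bounds are
    inclusive and must satisfy lo <= hi when both are given.
    """

    rank_selection: tuple[str, str] | None = None
    size_range: Range | None = None
    gc_range: Range | None = None
    chromosome_range: Range | None = None
    plasmid_range: Range | None = None
    gene_range: Range | None = None
    protein_range: Range | None = None

    def __post_init__(self):
        if self.rank_selection is not None:
            rank, _ = self.rank_selection
            if rank not in CANONICAL_RANKS:
                raise FilterSpecError(
                    f"unknown rank {rank!r}; expected one of {', '.join(CANONICAL_RANKS)}"
                )
        for name in _RANGE_ATTR:
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if lo is not None and hi is not None and lo > hi:
                raise FilterSpecError(f"{name}: lo {lo} > hi {hi}")

    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in _dc_fields(self))

    def to_flat(self) -> dict[str, str]:
        """Serialize to a flat key=value mapping (the CLI flag grammar)."""
        flat: dict[str, str] = {}
        if self.rank_selection is not None:
            flat["rank"] = f"{self.rank_selection[0]}={self.rank_selection[1]}"
        for name in _RANGE_ATTR:
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                key = name.removesuffix("_range")
                flat[key] = f"{'' if lo is None else lo}:{'' if hi is None else hi}"
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "FilterSpec":
        kwargs: dict = {}
        for key, value in flat.items():
            if key == "rank":
                rank, sep, taxon = value.partition("=")
                if not sep or not taxon:
                    raise FilterSpecError(f"rank selection must look like rank=Taxon, got {value!r}")
                kwargs["rank_selection"] = (rank.strip().lower(), taxon.strip())
            elif f"{key}_range" in _RANGE_ATTR:
                kwargs[f"{key}_range"] = parse_range(value)
            else:
                raise FilterSpecError(f"unknown filter key {key!r}")
        return cls(**kwargs)


def parse_range(text: str) -> Range:
    """Parse the ``lo:hi`` grammar; either side may be omitted."""
    lo_s, sep, hi_s = text.partition(":")
    if not sep:
        raise FilterSpecError(f"range must look like lo:hi (either side omissible), got {text!r}")
    try:
        lo = float(lo_s) if lo_s.strip() else None
        hi = float(hi_s) if hi_s.strip() else None
    except ValueError:
        raise FilterSpecError(f"non-numeric range bound in {text!r}") from None
    return (lo, hi)


def _in_range(value, rng: Range) -> bool:
    if value is None:
        return False  # missing value fails the clause
    lo, hi = rng
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def apply_filters(records: list[CuratedRecord], spec: FilterSpec) -> list[CuratedRecord]:
    """Return the records satisfying every present clause, in input order."""
    out = []
    n_missing_excluded = 0
    for rec in records:
        keep = True
        if spec.rank_selection is not None:
            rank, wanted = spec.rank_selection
            if getattr(rec, _RANK_ATTR[rank]).casefold() != wanted.casefold():
                keep = False
        if keep:
            for name, attr in _RANGE_ATTR.items():
                rng = getattr(spec, name)
                if rng is None:
                    continue
                value = getattr(rec, attr)
                if not _in_range(value, rng):
                    if value is None:
                        n_missing_excluded += 1
                    keep = False
                    break
        if keep:
            out.append(rec)
    if n_missing_excluded:
        logger.info("%d record(s) excluded for missing filtered features", n_missing_excluded)
    return out
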