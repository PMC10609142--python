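"""Descriptive statistics over curated genome metadata.

Five-number summaries (quartiles by linear interpolation between order
statistics), pairwise-complete Pearson correlation matrices, per-rank
distribution tables, submission-year histograms, half-up-rounded
prevalence percentages, and the 2x2 Pearson chi-square test of
independence used to ask whether multichromosomal genomes bear plasmids
at a different rate than single-chromosome genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .curation import CuratedRecord
from .errors import ProkmetaError
from .replicon import RepliconSet, has_plasmid, is_multichromosomal
from .taxonomy import CANONICAL_RANKS

#: Numeric feature attributes usable for boxplots / correlations.
NUMERIC_FEATURES = ("size_mb", "gc_percent", "n_chromosomes", "n_plasmids", "genes", "proteins")

_RANK_ATTR = {r: ("class_" if r == "class" else r) for r in CANONICAL_RANKS}


@dataclass(frozen=True)
class BoxplotStats:
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete Pearson r per feature pair.

    ``r[i, j]`` is NaN where the correlation is undefined (fewer than two
    complete cases, or zero variance) — deliberately distinct from 0.
    ``n[i, j]`` is the number of complete cases used for the pair.
    """

    features: tuple[str, ...]
    r: np.ndarray
    n: np.ndarray


@dataclass(frozen=True)
class RankDistribution:
    rank: str
    items: tuple[tuple[str, int], ...]  # sorted by count desc, then name asc

    def top_n(self, n: int) -> "RankDistribution":
        return RankDistribution(rank=self.rank, items=self.items[:n])


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    continuity_correction: bool


def boxplot_stats(values) -> BoxplotStats:
    """Five-number summary + mean; missing values (None/NaN) dropped first.

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    if arr.size == 0:
        raise ProkmetaError("boxplot_stats requires at least one non-missing value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return BoxplotStats(
        n=int(arr.size),
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
    )


def feature_values(records: list[CuratedRecord], feature: str) -> list[float | None]:
    if feature not in NUMERIC_FEATURES:
        raise ProkmetaError(f"unknown numeric feature {feature!r}; expected one of {NUMERIC_FEATURES}")
    return [getattr(rec, feature) for rec in records]


def pearson_matrix(records: list[CuratedRecord], features: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation over the named features.

    Deletion is pairwise (not listwise) so one missing feature does not
    shrink every pair; the per-pair n makes the choice auditable.
    """
    if len(features) < 2:
        raise ProkmetaError("pearson_matrix requires at least two features")
    cols = {f: pd.array(feature_values(records, f), dtype="Float64") for f in features}
    df = pd.DataFrame(cols).astype(float)  # pd.NA -> NaN
    k = len(features)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = df.iloc[:, [i, j]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 2:
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # zero variance: undefined, stays NaN
            if i == j:
                r[i, j] = 1.0
            else:
                r[i, j] = r[j, i] = float(_sps.pearsonr(x, y).statistic)
    return CorrelationMatrix(features=tuple(features), r=r, n=n)


def submissions_by_year(records: list[CuratedRecord]) -> list[tuple[object, int]]:
    """Counts per release-date calendar year, ascending; records with a
    missing date go to a trailing ``"unknown"`` bucket."""
    years: dict[int, int] = {}
    unknown = 0
    for rec in records:
        if rec.release_date is None:
            unknown += 1
        else:
            years[rec.release_date.year] = years.get(rec.release_date.year, 0) + 1
    out: list[tuple[object, int]] = [(y, years[y]) for y in sorted(years)]
    if unknown:
        out.append(("unknown", unknown))
    return out


def distribution_by_rank(
    records: list[CuratedRecord], rank: str, top_n: int | None = None
) -> RankDistribution:
    """Per-taxon genome counts at one canonical rank.

    Includes the "unclassified" bucket; sorted by count descending, then
    taxon name ascending; ``top_n`` truncates after sorting.
    """
    if rank not in CANONICAL_RANKS:
        raise ProkmetaError(f"unknown rank {rank!r}; expected one of {', '.join(CANONICAL_RANKS)}")
    attr = _RANK_ATTR[rank]
    counts: dict[str, int] = {}
    for rec in records:
        name = getattr(rec, attr)
        counts[name] = counts.get(name, 0) + 1
    items = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    dist = RankDistribution(rank=rank, items=items)
    return dist.top_n(top_n) if top_n is not None else dist


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals`` places."""
    if denominator <= 0:
        raise ProkmetaError("proportion_percent requires a positive denominator")
    if not 0 <= numerator <= denominator:
        raise ProkmetaError("numerator must lie in [0, denominator]")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def chi_square_2x2(table, continuity_correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    df = 1; the p-value is the upper tail of the chi-square distribution.
    Yates continuity correction is off by default and exposed as a flag.
    All four marginal sums must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ProkmetaError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ProkmetaError("table counts must be nonnegative")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ProkmetaError("every row and column marginal must be positive")
    res = _sps.chi2_contingency(arr, correction=continuity_correction)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=1,
        p=float(res.pvalue),
        table=tuple(tuple(int(v) for v in row) for row in arr),
        continuity_correction=continuity_correction,
    )


def multichromosome_plasmid_table(records: list[CuratedRecord]) -> np.ndarray:
    """Cross-tabulate multichromosomal (rows: yes/no) against
    plasmid-bearing (columns: yes/no) from curated replicon counts."""
    table = np.zeros((2, 2), dtype=int)
    for rec in records:
        rs = _counts_as_set(rec)
        i = 0 if is_multichromosomal(rs) else 1
        j = 0 if has_plasmid(rs) else 1
        table[i, j] += 1
    return table


def _counts_as_set(rec: CuratedRecord) -> RepliconSet:
    # The curated record stores counts, not entries; rebuild a minimal set
    # so the prevalence predicates stay pure functions of RepliconSet.
    from .replicon import KIND_CHROMOSOME, KIND_PLASMID, RepliconEntry

    entries = tuple(
        [RepliconEntry(KIND_CHROMOSOME, "chromosome", ()) for _ in range(rec.n_chromosomes)]
        + [RepliconEntry(KIND_PLASMID, "plasmid", ()) for _ in range(rec.n_plasmids)]
    )
    return RepliconSet(entries=entries)
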