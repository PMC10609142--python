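"""Descriptive statistics against independent closed-form oracles."""

import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prokmeta.errors import ProkmetaError
from prokmeta.stats import (
    boxplot_stats,
    chi_square_2x2,
    distribution_by_rank,
    multichromosome_plasmid_table,
    pearson_matrix,
    proportion_percent,
    submissions_by_year,
)

from conftest import make_curated


# --- boxplot -------------------------------------------------------------

def test_boxplot_odd_length_closed_form():
    bp = boxplot_stats([1, 2, 3, 4, 5])
    assert (bp.minimum, bp.q1, bp.median, bp.q3, bp.maximum) == (1, 2, 3, 4, 5)
    assert bp.mean == 3 and bp.n == 5


def test_boxplot_single_value_degenerate():
    bp = boxplot_stats([7])
    assert bp.minimum == bp.q1 == bp.median == bp.q3 == bp.maximum == bp.mean == 7


def test_boxplot_drops_missing_then_requires_one_value():
    assert boxplot_stats([None, 2.0, float("nan"), 4.0]).n == 2
    with pytest.raises(ProkmetaError):
        boxplot_stats([None, float("nan")])


def test_boxplot_median_matches_sort_oracle():
    rng = np.random.default_rng(5)
    values = np.exp(rng.normal(np.log(4.24), 0.5, size=1000))
    bp = boxplot_stats(values)
    s = np.sort(values)
    median_oracle = (s[499] + s[500]) / 2  # even n: mean of middle order stats
    assert bp.median == median_oracle
    assert bp.minimum == s[0] and bp.maximum == s[-1]


def test_boxplot_invariant_ordering(curated_records):
    from prokmeta.stats import feature_values

    bp = boxplot_stats(feature_values(curated_records, "size_mb"))
    assert bp.minimum <= bp.q1 <= bp.median <= bp.q3 <= bp.maximum


# --- Pearson -------------------------------------------------------------

def _pearson_oracle(x, y):
    """Textbook covariance formula, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def _recs_from_columns(**cols):
    n = len(next(iter(cols.values())))
    return [
        make_curated(**{k: (None if v[i] is None else v[i]) for k, v in cols.items()})
        for i in range(n)
    ]


def test_exact_linearity_gives_r_one():
    x = list(range(10))
    recs = _recs_from_columns(size_mb=[float(v) + 1 for v in x],
                              gc_percent=[2.0 * v + 1 for v in x])
    cm = pearson_matrix(recs, ["size_mb", "gc_percent"])
    assert cm.r[0, 1] == pytest.approx(1.0)
    assert cm.n[0, 1] == 10


def test_constant_feature_is_undefined_not_zero():
    recs = _recs_from_columns(size_mb=[1.0, 1.0, 1.0], gc_percent=[10.0, 20.0, 30.0])
    cm = pearson_matrix(recs, ["size_mb", "gc_percent"])
    assert np.isnan(cm.r[0, 1])
    assert np.isnan(cm.r[0, 0])  # diagonal of a zero-variance feature too
    assert cm.r[1, 1] == 1.0


def test_matches_covariance_oracle_to_1e12():
    rng = np.random.default_rng(12)
    x = rng.normal(4, 1, size=50)
    y = 0.5 * x + rng.normal(0, 1, size=50)
    recs = _recs_from_columns(size_mb=list(x), gc_percent=list(y))
    cm = pearson_matrix(recs, ["size_mb", "gc_percent"])
    assert abs(cm.r[0, 1] - _pearson_oracle(x, y)) < 1e-12
    assert np.allclose(cm.r, cm.r.T, equal_nan=True)


def test_pairwise_complete_deletion_counts_per_pair():
    recs = _recs_from_columns(
        size_mb=[1.0, 2.0, None, 4.0],
        gc_percent=[30.0, None, 50.0, 60.0],
        genes=[100, 200, 300, 400],
    )
    cm = pearson_matrix(recs, ["size_mb", "gc_percent", "genes"])
    assert cm.n[0, 1] == 2  # rows where both size and GC present
    assert cm.n[0, 2] == 3
    assert cm.n[2, 2] == 4


# --- year and rank tables ------------------------------------------------

def test_submissions_by_year_buckets():
    recs = [
        make_curated(release_date=datetime.date(1995, 5, 1)),
        make_curated(release_date=datetime.date(1995, 8, 2)),
        make_curated(release_date=datetime.date(1996, 1, 3)),
    ]
    assert submissions_by_year(recs) == [(1995, 2), (1996, 1)]
    only_missing = [make_curated(release_date=None)]
    assert submissions_by_year(only_missing) == [("unknown", 1)]


def test_year_counts_conserve_total(curated_records):
    table = submissions_by_year(curated_records)
    assert sum(c for _, c in table) == len(curated_records)


def test_distribution_sorted_and_conserving():
    recs = [
        make_curated(phylum="A"),
        make_curated(phylum="A"),
        make_curated(phylum="B"),
        make_curated(phylum="unclassified"),
    ]
    dist = distribution_by_rank(recs, "phylum")
    assert dist.items == (("A", 2), ("B", 1), ("unclassified", 1))
    assert distribution_by_rank(recs, "phylum", top_n=1).items == (("A", 2),)
    assert sum(c for _, c in dist.items) == len(recs)


def test_distribution_ties_break_by_name():
    recs = [make_curated(genus=g) for g in ["Zeta", "Alpha", "Zeta", "Alpha"]]
    dist = distribution_by_rank(recs, "genus")
    assert dist.items == (("Alpha", 2), ("Zeta", 2))


def test_distribution_unknown_rank_errors(curated_records):
    with pytest.raises(ProkmetaError):
        distribution_by_rank(curated_records, "kingdom")


def test_distribution_matches_fixture_manifest(curated_records, fixture_result):
    for rank in ("phylum", "genus", "species"):
        dist = distribution_by_rank(curated_records, rank)
        expected = fixture_result.manifest.aggregates["rank_histograms"][rank]
        assert dict(dist.items) == expected


# --- proportions ---------------------------------------------------------

@pytest.mark.parametrize(
    "num, den, expected",
    [(1633, 32603, 5.0), (14279, 32603, 43.8), (0, 100, 0.0)],
)
def test_proportion_percent_examples(num, den, expected):
    assert proportion_percent(num, den, 1) == expected


def test_proportion_percent_half_up_rounding():
    assert proportion_percent(1, 16, 1) == 6.3  # 6.25 rounds up, not banker's
    assert proportion_percent(5, 1000, 1) == 0.5


def test_proportion_percent_errors():
    with pytest.raises(ProkmetaError):
        proportion_percent(1, 0, 1)
    with pytest.raises(ProkmetaError):
        proportion_percent(5, 4, 1)


@given(st.integers(1, 10**6).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
@settings(max_examples=100, deadline=None)
def test_proportion_and_complement_sum_to_100(pair):
    n, a = pair
    total = proportion_percent(a, n, 1) + proportion_percent(n - a, n, 1)
    assert abs(total - 100.0) <= 0.1  # up to one rounding quantum


# --- chi-square ----------------------------------------------------------

def _chi2_oracle(a, b, c, d):
    """Closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def test_observed_equals_expected_gives_zero():
    res = chi_square_2x2([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p == 1.0 and res.df == 1


def test_matches_closed_form_oracle():
    res = chi_square_2x2([[20, 10], [10, 20]])
    assert res.statistic == pytest.approx(_chi2_oracle(20, 10, 10, 20), abs=1e-12)


@given(st.tuples(*[st.integers(1, 200)] * 4))
@settings(max_examples=100, deadline=None)
def test_chi_square_properties(cells):
    a, b, c, d = cells
    res = chi_square_2x2([[a, b], [c, d]])
    assert res.statistic == pytest.approx(_chi2_oracle(a, b, c, d), rel=1e-9)
    # symmetry: swapping both rows and both columns leaves the statistic unchanged
    swapped = chi_square_2x2([[d, c], [b, a]])
    assert swapped.statistic == pytest.approx(res.statistic, rel=1e-12)
    # Yates correction only ever shrinks the statistic
    yates = chi_square_2x2([[a, b], [c, d]], continuity_correction=True)
    assert yates.statistic <= res.statistic + 1e-12
    assert 0.0 <= res.p <= 1.0


def test_zero_marginal_errors():
    with pytest.raises(ProkmetaError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_cross_tabulation_covers_all_four_cells():
    recs = [
        make_curated(n_chromosomes=2, n_plasmids=1),
        make_curated(n_chromosomes=2, n_plasmids=0),
        make_curated(n_chromosomes=1, n_plasmids=3),
        make_curated(n_chromosomes=1, n_plasmids=0),
    ]
    table = multichromosome_plasmid_table(recs)
    assert table.tolist() == [[1, 1], [1, 1]]
    assert chi_square_2x2(table).statistic == 0.0
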