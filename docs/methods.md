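# Methods

## Problem and scope

`prokmeta` curates per-assembly metadata of complete prokaryotic genomes
(CPGs) from the tab-delimited NCBI GENOME_REPORTS prokaryote table and
computes the descriptive statistics a comparative genomicist asks of that
table: five-number feature summaries, Pearson correlations between genomic
features, genome counts by taxonomic group and by submission year,
prevalence percentages of multichromosomal and plasmid-bearing genomes,
and a 2×2 chi-square test of whether multichromosomality and plasmid
carriage are independent. Everything runs offline: lineage resolution uses
a local NCBI taxdump rather than a network taxonomy service, and a seeded
synthetic-data generator stands in for the live report in all tests.

## Curation model

A source row is *complete* when its assembly-level `Status` equals
`Complete Genome` after whitespace trimming, case-insensitively. This is
the single selection constant of the pipeline; no other quality filter is
applied, and complete genomes lacking an FTP path are kept (the field may
simply be missing). Genome size stays in megabases as published; GC% is a
percentage in (0, 100]. Values violating these ranges, and any
unparseable numeric or date cell, are coerced to missing in lenient mode
(the default) with a line-numbered log entry; strict mode aborts instead.
Column identity comes from header names, never positions, so column
permutations of the source are harmless. The missing-value sentinel is
`-`; empty cells are treated the same.

### Replicon counting

The `Replicons` cell is split on `;`; each entry is `descriptor` or
`descriptor:acc1/acc2`. Classification is by descriptor, lowercased: any
descriptor containing the word `plasmid` (this catches `megaplasmid` and
named plasmids) is a plasmid; otherwise a descriptor starting with
`chromosome` (this catches `chromosome 2`, `chromosome II`, and
`chromosome segment`-style labels) is a chromosome; anything else counts
as `other` and is logged, never silently discarded. The source provides no
grammar for this field, so substring rules over the observed vocabulary
are the design choice; the `other` bucket and its log make
misclassification auditable. A genome is *multichromosomal* when it has
two or more chromosome entries and *plasmid-bearing* when it has at least
one plasmid entry; both predicates are pure functions of the parsed set.
A missing replicon cell yields zero counts, which means such genomes fall
in the single-chromosome, plasmid-free margin of downstream tables — a
deliberate, logged convention rather than row removal.

### Taxonomy

Lineages are resolved by walking parent pointers in a loaded
`nodes.dmp`/`names.dmp` (optionally `merged.dmp`) taxdump. The seven
canonical slots are superkingdom, phylum, class, order, family, genus,
species; the rank string `domain` found in newer dumps fills the
superkingdom slot. Slots no ancestor resolves carry the visible sentinel
`unclassified` so distribution tables have an explicit bucket. Records
whose taxid the dump cannot resolve are *retained* with an
all-unclassified lineage and logged: dropping them would silently change
every denominator relative to the source file. Loading validates the dump
(dangling parents and parent-pointer cycles abort with the offending
taxid); resolution is deterministic and memoised per database.

## Filtering

A filter is the conjunction of at most one rank selection
(case-insensitive exact match on one lineage slot) and inclusive numeric
ranges over genome size, GC%, chromosome, plasmid, gene and protein
counts; either range bound may be open. A record missing a value for a
filtered feature is excluded by that clause, so the denominator of any
prevalence computed from a filtered table equals the table's row count;
the exclusion count is logged. These semantics give the algebraic laws the
tests enforce: adding a clause never grows the result, clause order is
irrelevant, and filtering is idempotent.

## Statistics

* Quartiles use linear interpolation between order statistics
  (`numpy.percentile(..., method="linear")`). The convention is pinned so
  box-plot tables are reproducible bit-for-bit.
* Correlations are pairwise-complete Pearson r: each feature pair uses
  every row where both features are present, so one missing feature does
  not shrink all pairs; the per-pair n is reported. A pair with fewer than
  two complete cases or zero variance is *undefined* (NaN), deliberately
  distinct from r = 0.
* Reported percentages are `100·numerator/denominator` rounded half-up
  (decimal, not banker's) to the requested places, matching the
  presentation convention of published prevalence figures.
* The 2×2 chi-square test is the Pearson statistic with df = 1 and an
  upper-tail p-value, computed via `scipy.stats.chi2_contingency`. The
  Yates continuity correction is off by default — at the sample sizes this
  table is built from (tens of thousands of genomes) it changes nothing
  material — and exposed as a flag. Tests verify the statistic against the
  closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).

## Synthetic data generator

The generator emits a genome report, a matching mini-taxdump covering
every emitted taxid, and a ground-truth manifest; the manifest is the
oracle every pipeline stage is checked against. Defaults describe a
population with the scales reported for real CPG metadata:

| parameter | default | rationale |
|---|---|---|
| genome size | log-normal, median 4.24 Mb, σ(log) 0.55 | median of real complete bacterial genomes; σ spans the reported 0.11–16 Mb range |
| GC% | normal(50.7, 10) truncated to [13.5, 75.6] | reported median and observed extremes |
| chromosomes | P(1)=0.95, P(2)=0.04, P(3)=0.01 | ~5% of complete genomes are multichromosomal |
| plasmids | P(0)=0.562, P(1)=0.25, P(2)=0.13, P(3)=0.058 | ~44% plasmid-bearing |
| release years | uniform 1995–2023 | complete-genome submission era |
| fraction complete | 0.4 | report mixes complete and draft levels |
| missingness | 1–5% per optional column | sparse holes as in the live table |

Complete status is allocated deterministically — exactly ⌊f·n⌋ records,
chosen by a seeded shuffle — so the complete count is exact rather than
binomial. Replicon strings are built from the ground-truth counts through
the same descriptor vocabulary the parser accepts, and a configurable
fraction (default 0.2) uses adversarial variants (numbered and Roman
chromosome labels, `megaplasmid`, stray whitespace, irregular separators)
to exercise the grammar. When a missingness draw blanks the replicon
cell, the manifest records the *effective* counts (zeros), i.e. what any
parser of the emitted file can know. The seed fixes all output
byte-for-byte.

Deliberately not emulated: correlation between lineage and genomic
features (features are drawn independently of taxonomy), multiple
assemblies per strain, and real accession formats. Passing tests
therefore demonstrate correctness of counting, filtering and statistics
on files of the right dialect and scale — not that any biological signal
(e.g. the real size–GC correlation of r ≈ 0.6, or phylum composition) is
recovered, which would require the live snapshot.

## Problem sizes and numerical choices

The shared test fixture uses 600 records; the end-to-end
manifest-equivalence check uses 10,000; parameter recovery uses 5,000
(median size within 5% of the configured log-normal median, GC mean
within 3·sd/√n of the analytic truncated-normal mean — the truncation
shifts the expectation ~0.18 below the untruncated centre, so the
analytic mean is the correct recovery target). Dates parse as
`YYYY/MM/DD` or `YYYY-MM-DD`; anything else is missing plus a log entry.
Distribution tables sort by count descending, then name ascending, so
top-N truncation is deterministic under ties.

## Known limitations

* The replicon grammar is heuristic; descriptors that are neither
  chromosome-like nor plasmid-like land in `other` and rely on the log
  for review.
* Only the prokaryote genome-report dialect is supported (not the
  eukaryote/virus reports), and sequence data are never downloaded — the
  curated table only carries FTP paths.
* The curated table keeps one row per assembly; no deduplication across
  assemblies of the same strain or species is attempted.
* Rank selection accepts a single value per invocation; multi-value
  selection is an extension point, not implemented.
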