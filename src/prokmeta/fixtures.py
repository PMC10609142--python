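"""Seeded synthetic genome-report + mini-taxdump generator with a
ground-truth manifest.

The generator emits the same file dialects the readers consume — a
tab-delimited ``#``-headed genome report and matching ``nodes.dmp`` /
``names.dmp`` files covering every taxid used — together with a Manifest
recording per-record ground truth (status, effective chromosome/plasmid
counts, lineage, release year) and the aggregate truths every pipeline
stage is checked against (complete count, multichromosomal count,
plasmid-bearing count, per-rank histograms, year histogram).

Default feature distributions echo the scales reported for real complete
prokaryotic genomes: log-normal genome size with median 4.24 Mb, truncated
normal GC% centred at 50.7 with bounds [13.5, 75.6], roughly 5% of genomes
multichromosomal and roughly 44% plasmid-bearing, release years 1995-2023.
Features are drawn independently of lineage; see docs/methods.md for what
that does and does not exercise.

The seed fixes the full output byte-for-byte.  Complete/non-complete
status is assigned by deterministic allocation — exactly ``floor(f * n)``
records, chosen by a seeded shuffle, are complete — so the complete count
is exact rather than binomial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ProkmetaError
from .taxonomy import CANONICAL_RANKS

_REPORT_HEADER = [
    "#Organism/Name",
    "TaxID",
    "BioProject",
    "Group",
    "SubGroup",
    "Size (Mb)",
    "GC%",
    "Replicons",
    "Genes",
    "Proteins",
    "Release Date",
    "Status",
    "Center",
    "Assembly Accession",
    "FTP Path",
    "Strain",
]

_NONCOMPLETE_STATUSES = ("Scaffold", "Contig", "Chromosome")


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study population; defaults mirror the
    real complete-genome metadata scales (see module docstring)."""

    n_records: int = 1000
    fraction_complete: float = 0.4
    size_median_mb: float = 4.24
    size_sigma: float = 0.55  # sigma of log size
    gc_mean: float = 50.7
    gc_sd: float = 10.0
    gc_bounds: tuple[float, float] = (13.5, 75.6)
    chromosome_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.95, 2: 0.04, 3: 0.01}
    )
    plasmid_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.562, 1: 0.25, 2: 0.13, 3: 0.058}
    )
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "size_mb": 0.01,
            "gc_percent": 0.01,
            "replicons": 0.01,
            "genes": 0.02,
            "proteins": 0.02,
            "release_date": 0.01,
            "ftp_path": 0.05,
        }
    )
    n_phyla: int = 6
    n_genera: int = 30
    n_species: int = 120
    year_range: tuple[int, int] = (1995, 2023)
    adversarial_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ProkmetaError("n_records must be positive")
        if not 0.0 <= self.fraction_complete <= 1.0:
            raise ProkmetaError("fraction_complete must lie in [0, 1]")
        if self.size_median_mb <= 0 or self.size_sigma < 0:
            raise ProkmetaError("size distribution parameters must be positive")
        for name, probs in (("chromosome_probs", self.chromosome_probs),
                            ("plasmid_probs", self.plasmid_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ProkmetaError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ProkmetaError(f"{name} has a negative probability")
        for col, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ProkmetaError(f"missingness[{col!r}] must lie in [0, 1]")
        if not (1 <= self.n_phyla <= self.n_genera <= self.n_species):
            raise ProkmetaError("taxonomy shape must satisfy n_phyla <= n_genera <= n_species")
        if self.year_range[0] > self.year_range[1]:
            raise ProkmetaError("year_range must be ascending")
        if not 0.0 <= self.adversarial_fraction <= 1.0:
            raise ProkmetaError("adversarial_fraction must lie in [0, 1]")


@dataclass
class Manifest:
    """Ground truth of an emitted fixture: one row per record plus the
    aggregates the pipeline must reproduce exactly."""

    records: pd.DataFrame
    aggregates: dict

    def save(self, records_path: Path, summary_path: Path) -> None:
        self.records.to_csv(records_path, index=False)
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(self.aggregates, fh, indent=2, sort_keys=True)


@dataclass
class FixtureResult:
    report_path: Path
    nodes_path: Path
    names_path: Path
    manifest_path: Path
    summary_path: Path
    manifest: Manifest


# ---------------------------------------------------------------------------
# Taxonomy construction
# ---------------------------------------------------------------------------


def _build_taxonomy(cfg: FixtureConfig):
    """Deterministic seven-rank tree: root -> 2 superkingdoms -> phyla ->
    one class and one order per phylum -> one family per genus -> genera
    -> species.  Returns (nodes, names, species_info)."""
    nodes: list[tuple[int, int, str]] = [(1, 1, "no rank")]
    names: dict[int, str] = {1: "root"}
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        tid = next_id
        next_id += 1
        nodes.append((tid, parent, rank))
        names[tid] = name
        return tid

    sk_ids = [add(1, "superkingdom", "Bacteria"), add(1, "superkingdom", "Archaea")]
    sk_names = {sk_ids[0]: "Bacteria", sk_ids[1]: "Archaea"}

    phylum_meta = []  # (order_taxid, lineage names so far)
    for p in range(cfg.n_phyla):
        sk = sk_ids[0] if p % 5 != 4 else sk_ids[1]  # every 5th phylum archaeal
        pname = f"Phylum{p + 1:02d}"
        pid = add(sk, "phylum", pname)
        cid = add(pid, "class", f"{pname}_classis")
        oid = add(cid, "order", f"{pname}_ales")
        phylum_meta.append(
            (oid, {"superkingdom": sk_names[sk], "phylum": pname,
                   "class": f"{pname}_classis", "order": f"{pname}_ales"})
        )

    genus_meta = []
    for g in range(cfg.n_genera):
        oid, lin = phylum_meta[g % cfg.n_phyla]
        gname = f"Genus{g + 1:03d}"
        fid = add(oid, "family", f"{gname}aceae")
        gid = add(fid, "genus", gname)
        genus_meta.append((gid, {**lin, "family": f"{gname}aceae", "genus": gname}))

    species_info = []  # (taxid, species name, full lineage dict)
    for s in range(cfg.n_species):
        gid, lin = genus_meta[s % cfg.n_genera]
        sname = f"{lin['genus']} specius{s + 1:04d}"
        sid = add(gid, "species", sname)
        species_info.append((sid, sname, {**lin, "species": sname}))

    return nodes, names, species_info


def _write_taxdump(nodes, names, nodes_path: Path, names_path: Path) -> None:
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{names[taxid]}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# Replicon string construction
# ---------------------------------------------------------------------------

_ROMAN = ("I", "II", "III", "IV", "V")


def _replicon_string(n_chrom: int, n_plas: int, idx: int, adversarial: bool, rng) -> str:
    parts = []
    for c in range(n_chrom):
        acc = f"NC_{idx:06d}{c}.1"
        if adversarial and n_chrom > 1:
            style = rng.integers(0, 3)
            if style == 0:
                label = f"chromosome {c + 1}"
            elif style == 1:
                label = f"chromosome {_ROMAN[c]}"
            else:
                label = f" chromosome {c + 1} "  # stray whitespace
        else:
            label = "chromosome" if n_chrom == 1 else f"chromosome {c + 1}"
        parts.append(f"{label}:{acc}")
    for p in range(n_plas):
        acc = f"NC_{idx:06d}{9 - p}.1"
        if adversarial and p == 0 and rng.integers(0, 2) == 0:
            label = f"megaplasmid p{idx % 97}"
        else:
            label = f"plasmid p{chr(ord('A') + p)}{idx % 97}"
        parts.append(f"{label}:{acc}")
    sep = " ; " if adversarial and rng.integers(0, 2) == 0 else "; "
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> FixtureResult:
    """Emit report + taxdump + manifest under ``out_dir``.

    Same config + seed -> byte-identical files.
    """
    config.validate()
    cfg = config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    nodes, names, species_info = _build_taxonomy(cfg)

    n = cfg.n_records
    # Deterministic complete-status allocation: exactly floor(f*n) complete.
    n_complete = math.floor(cfg.fraction_complete * n)
    perm = rng.permutation(n)
    complete = np.zeros(n, dtype=bool)
    complete[perm[:n_complete]] = True
    noncomplete_choice = rng.integers(0, len(_NONCOMPLETE_STATUSES), size=n)

    species_idx = rng.integers(0, cfg.n_species, size=n)
    size = np.round(
        np.exp(rng.normal(np.log(cfg.size_median_mb), cfg.size_sigma, size=n)), 4
    )
    size = np.maximum(size, 0.01)
    gc = rng.normal(cfg.gc_mean, cfg.gc_sd, size=n)
    lo, hi = cfg.gc_bounds
    while True:  # truncation by redraw
        bad = (gc < lo) | (gc > hi)
        if not bad.any():
            break
        gc[bad] = rng.normal(cfg.gc_mean, cfg.gc_sd, size=int(bad.sum()))
    gc = np.round(gc, 1)

    chrom_vals = np.array(sorted(cfg.chromosome_probs))
    chrom_p = np.array([cfg.chromosome_probs[k] for k in chrom_vals])
    n_chrom = rng.choice(chrom_vals, size=n, p=chrom_p)
    plas_vals = np.array(sorted(cfg.plasmid_probs))
    plas_p = np.array([cfg.plasmid_probs[k] for k in plas_vals])
    n_plas = rng.choice(plas_vals, size=n, p=plas_p)

    genes = np.maximum((size * 1000 * 0.9 + rng.normal(0, 50, size=n)).astype(int), 10)
    proteins = np.maximum(genes - rng.integers(20, 80, size=n), 1)

    y0, y1 = cfg.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)

    adversarial = rng.random(n) < cfg.adversarial_fraction
    miss = {col: rng.random(n) < rate for col, rate in cfg.missingness.items()}

    report_path = out_dir / "report.txt"
    manifest_rows = []
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REPORT_HEADER) + "\n")
        for i in range(n):
            taxid, sname, lineage = species_info[species_idx[i]]
            organism = f"{sname} strain S{i + 1:05d}"
            status = (
                "Complete Genome"
                if complete[i]
                else _NONCOMPLETE_STATUSES[noncomplete_choice[i]]
            )
            repl = _replicon_string(int(n_chrom[i]), int(n_plas[i]), i, bool(adversarial[i]), rng)
            repl_missing = miss.get("replicons", np.zeros(n, bool))[i]
            date_missing = miss.get("release_date", np.zeros(n, bool))[i]
            cells = [
                organism,
                str(taxid),
                f"PRJNA{100000 + i}",
                "Bacteria" if lineage["superkingdom"] == "Bacteria" else "Archaea",
                lineage["phylum"],
                "-" if miss.get("size_mb", np.zeros(n, bool))[i] else f"{size[i]:.4f}",
                "-" if miss.get("gc_percent", np.zeros(n, bool))[i] else f"{gc[i]:.1f}",
                "-" if repl_missing else repl,
                "-" if miss.get("genes", np.zeros(n, bool))[i] else str(int(genes[i])),
                "-" if miss.get("proteins", np.zeros(n, bool))[i] else str(int(proteins[i])),
                "-" if date_missing else f"{years[i]}/{months[i]:02d}/{days[i]:02d}",
                status,
                "SynthCenter",
                f"GCA_{900000000 + i}.1",
                "-"
                if miss.get("ftp_path", np.zeros(n, bool))[i]
                else f"https://ftp.example.org/genomes/all/GCA_{900000000 + i}.1",
                f"S{i + 1:05d}",
            ]
            fh.write("\t".join(cells) + "\n")
            # Effective counts: what a parser sees (missing cell -> zeros).
            eff_chrom = 0 if repl_missing else int(n_chrom[i])
            eff_plas = 0 if repl_missing else int(n_plas[i])
            manifest_rows.append(
                {
                    "index": i,
                    "organism_name": organism,
                    "taxid": taxid,
                    "status": status,
                    "complete": bool(complete[i]),
                    "n_chromosomes": eff_chrom,
                    "n_plasmids": eff_plas,
                    "size_mb": np.nan if miss.get("size_mb", np.zeros(n, bool))[i] else size[i],
                    "gc_percent": np.nan
                    if miss.get("gc_percent", np.zeros(n, bool))[i]
                    else gc[i],
                    "year": -1 if date_missing else int(years[i]),
                    **{r: lineage[r] for r in CANONICAL_RANKS},
                }
            )

    mdf = pd.DataFrame(manifest_rows)
    comp = mdf[mdf["complete"]]
    aggregates = {
        "n_records": int(n),
        "n_complete": int(comp.shape[0]),
        "n_multichromosomal": int((comp["n_chromosomes"] >= 2).sum()),
        "n_plasmid_bearing": int((comp["n_plasmids"] >= 1).sum()),
        "rank_histograms": {
            r: {k: int(v) for k, v in comp[r].value_counts().items()} for r in CANONICAL_RANKS
        },
        "year_histogram": {
            ("unknown" if y == -1 else str(y)): int(c)
            for y, c in comp["year"].value_counts().sort_index().items()
        },
        "seed": int(cfg.seed),
    }
    manifest = Manifest(records=mdf, aggregates=aggregates)

    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    _write_taxdump(nodes, names, nodes_path, names_path)
    manifest_path = out_dir / "manifest.csv"
    summary_path = out_dir / "manifest_summary.json"
    manifest.save(manifest_path, summary_path)

    return FixtureResult(
        report_path=report_path,
        nodes_path=nodes_path,
        names_path=names_path,
        manifest_path=manifest_path,
        summary_path=summary_path,
        manifest=manifest,
    )
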