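import datetime

import pytest

from prokmeta import (
    FixtureConfig,
    curate,
    generate_fixture,
    load_taxdump,
    read_genome_report,
)
from prokmeta.curation import CuratedRecord


@pytest.fixture(scope="session")
def fixture_result(tmp_path_factory):
    """One medium synthetic study population shared across the suite."""
    cfg = FixtureConfig(n_records=600, seed=11)
    return generate_fixture(cfg, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def taxdb(fixture_result):
    return load_taxdump(fixture_result.nodes_path, fixture_result.names_path)


@pytest.fixture(scope="session")
def raw_records(fixture_result):
    records, _ = read_genome_report(fixture_result.report_path)
    return records


@pytest.fixture(scope="session")
def curated_records(raw_records, taxdb):
    records, _ = curate(raw_records, taxdb)
    return records


def make_curated(**overrides) -> CuratedRecord:
    """Hand-built curated record with sensible defaults for unit tests."""
    base = dict(
        organism_name="Examplea testii strain T1",
        taxid=100,
        size_mb=4.2,
        gc_percent=50.0,
        replicons_raw="chromosome:NC_000001.1",
        n_chromosomes=1,
        n_plasmids=0,
        genes=4000,
        proteins=3900,
        release_date=datetime.date(2020, 1, 15),
        ftp_path="https://ftp.example.org/genomes/GCA_1.1",
        superkingdom="Bacteria",
        phylum="PhylumA",
        class_="ClassA",
        order="OrderA",
        family="FamilyA",
        genus="Examplea",
        species="Examplea testii",
    )
    base.update(overrides)
    return CuratedRecord(**base)
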