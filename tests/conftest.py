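import pytest

from siftsmap.ccd import ComponentDictionary
from siftsmap.fixtures import (
    StructureSpec,
    make_reference_set,
    make_toy_ccd,
    make_toy_structure,
    toy_lineage_rows,
)
from siftsmap.mmcif_io import parse_polymer_entities
from siftsmap.scoring import LineageRecord


@pytest.fixture(scope="session")
def toy_ccd():
    return ComponentDictionary.from_text(make_toy_ccd())


@pytest.fixture(scope="session")
def lineages():
    return {
        row[0]: LineageRecord(
            tax_id=row[0], species_taxid=row[1], genus_taxid=row[2],
            family_taxid=row[3], order_taxid=row[4],
        )
        for row in toy_lineage_rows()
    }


@pytest.fixture()
def simple_entity():
    cif = make_toy_structure(StructureSpec(sequence="ACDEFGHIKLMNPQRSTVWY"))
    return parse_polymer_entities(cif)[0]


@pytest.fixture(scope="session")
def refset(tmp_path_factory):
    """A small reference set bracketing the identity cutoff, with mixed
    datasets and taxa, built into an on-disk index."""
    fixture = make_reference_set(
        4,
        mutation_rates=[0.0, 0.05, 0.15, 0.0],
        datasets=["sp", "sp", "tr", "tr"],
        tax_ids=[101, 102, 101, 101],
        annotation_scores=[5, 3, 0, 2],
        xref_counts=[120, 3, 0, 7],
        protect_ends=5,
        seed=7,
    )
    directory = tmp_path_factory.mktemp("refset")
    paths = fixture.write(directory)
    return fixture, paths
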