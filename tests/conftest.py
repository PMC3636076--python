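import pytest

from musadiv.pipeline_io import GenotypeTable, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def small_table():
    """Four accessions x two loci covering het/hom/missing cells."""
    return GenotypeTable(
        accessions=["a1", "a2", "a3", "a4"],
        locus_names=["L01", "L02"],
        calls=[
            [(101, 105), (200,)],
            [(101,), (200, 210)],
            [(105,), None],
            [(101, 105), (210,)],
        ],
    )
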