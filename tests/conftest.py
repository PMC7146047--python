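import pytest

from genmeta import GeneticModel, build_contrast, load_fixture


@pytest.fixture(scope="session")
def total_studies():
    """The 12 rs10033900 total-AMD case-control studies."""
    return load_fixture("rs10033900_total")


@pytest.fixture(scope="session")
def by_type_studies():
    """The 11 neovascular / geographic-atrophy strata."""
    return load_fixture("rs10033900_by_type")


@pytest.fixture(scope="session")
def rs2_studies():
    """The 3 rs2285714 studies."""
    return load_fixture("rs2285714")


@pytest.fixture(scope="session")
def allele_tables(total_studies):
    """Allele-contrast 2x2 tables for the 12-study set."""
    return [build_contrast(s, GeneticModel.ALLELE) for s in total_studies]
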