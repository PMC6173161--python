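import pytest

from frogdiet import datasets
from frogdiet.simulate import generate_assemblage
from frogdiet.types import PredatorRecord, PreyItem


@pytest.fixture(scope="session")
def trait_table():
    return datasets.default_trait_table()


@pytest.fixture(scope="session")
def fixture_tables():
    return datasets.andaman_composition_tables()


@pytest.fixture(scope="session")
def fixture_matrix():
    return datasets.andaman_count_matrix()


@pytest.fixture(scope="session")
def assemblage():
    """One synthetic assemblage at the published study conditions."""
    return generate_assemblage(seed=42)


def make_record(ind_id, taxon="H_tigerinus", svl=100.0, prey=(), season="dry",
                habitat="agriculture", site="Webi"):
    """Terse builder: ``prey`` is a list of (taxon, volume) pairs."""
    stomach = [PreyItem(taxon=t, volume_mm3=v) for t, v in prey]
    return PredatorRecord(
        individual_id=ind_id, taxon=taxon, svl_mm=svl, site=site,
        habitat=habitat, season=season, stomach=stomach,
    )
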