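import pytest

from ylepop.genetics import GenotypeSpace, LociConfig
from ylepop.strategies import strategy_preset


@pytest.fixture(scope="session")
def base_space():
    """The 6-female / 12-male genotype space of the three-allele model."""
    return GenotypeSpace(LociConfig.base())


@pytest.fixture(scope="session")
def strain_b():
    """Engineered-strain baseline preset (editing, phenotype, released males)."""
    return strategy_preset("yle_dsx_b")
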