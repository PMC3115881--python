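import pytest

from mitocomp.composition import load_reference_cohort
from mitocomp.synthetic import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def genome7():
    """One deterministic synthetic mitogenome in the ancestral gene order."""
    return generate_genome(GenomeSpec(seed=7))


@pytest.fixture(scope="session")
def neuroptera_genome():
    """Synthetic genome carrying the trnC-before-trnW translocation."""
    return generate_genome(GenomeSpec(seed=3, gene_order="neuroptera"))


@pytest.fixture(scope="session")
def reference_cohort():
    """84-taxon published whole-mtDNA composition survey with printed labels."""
    return load_reference_cohort()
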