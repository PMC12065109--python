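import pytest

from porerules import ModificationScheme, gen_canonical_model


@pytest.fixture(scope="session")
def cg_scheme():
    """CpG methylation: modified C immediately before a G."""
    return ModificationScheme("CG", 0, "M")


@pytest.fixture(scope="session")
def gc_scheme():
    """GpC methylation: modified C immediately after a G."""
    return ModificationScheme("GC", 1, "M")


@pytest.fixture(scope="session")
def toy_scheme():
    """Single-base motif (any C can be modified) for 3-mer toy examples."""
    return ModificationScheme("C", 0, "M")


@pytest.fixture(scope="session")
def canonical6():
    return gen_canonical_model(6, seed=11)


@pytest.fixture(scope="session")
def canonical3():
    return gen_canonical_model(3, seed=11)
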