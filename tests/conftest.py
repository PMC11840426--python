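import pytest
from hypothesis import settings

from owlpellets import fixtures

settings.register_profile("suite", derandomize=True, database=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toorak_vectors():
    """Abundance vectors for all four Toorak collections."""
    return fixtures.load_all()


@pytest.fixture(scope="session")
def present_day_vectors(toorak_vectors):
    return {c: toorak_vectors[c] for c in fixtures.PRESENT_DAY}


@pytest.fixture(scope="session")
def initial_mammals(toorak_vectors):
    """Initial-collection mammal counts (135, 16, 46, 106, 2)."""
    return toorak_vectors["Initial"].mammal_counts()


@pytest.fixture(scope="session")
def tabulated_present_day():
    """Element-level reconstructions piped through the MNI pipeline."""
    from owlpellets.abundance import tabulate

    out = {}
    for cid in fixtures.PRESENT_DAY:
        records, meta = fixtures.element_records(cid)
        pellets, vec = tabulate(records, meta)
        out[cid] = (pellets, vec, meta)
    return out
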