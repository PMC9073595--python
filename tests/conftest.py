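import numpy as np
import pytest

from dienoneqsar.compounds import build_fixture_library
from dienoneqsar.synth import gen_mock_electronic_structure, gen_toy_conformers


@pytest.fixture(scope="session")
def library():
    return build_fixture_library()


@pytest.fixture(scope="session")
def records(library):
    return library[0]


@pytest.fixture(scope="session")
def records_by_id(records):
    return {r.id: r for r in records}


@pytest.fixture(scope="session")
def activity_table(library):
    return library[1]


@pytest.fixture(scope="session")
def toy_conformers():
    return gen_toy_conformers()


@pytest.fixture()
def mock_es():
    return gen_mock_electronic_structure(n_atoms=6, basis_per_atom=3, seed=7)


@pytest.fixture(scope="session")
def profile_24(records_by_id):
    """Full descriptor profile of compound 24 (computed once per session)."""
    from dienoneqsar.descriptors import descriptor_profile

    return descriptor_profile(records_by_id[24])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20191021)
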