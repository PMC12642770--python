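import pytest

from gifms.backend import MockBackend, MockOracleConfig
from gifms.chem import ExperimentSettings, parse_molecule
from gifms.io import FixtureConfig, generate_fixtures


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO")


@pytest.fixture(scope="session")
def glycine():
    return parse_molecule("NCC(=O)O")


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1")


@pytest.fixture(scope="session")
def toluene():
    return parse_molecule("Cc1ccccc1")


@pytest.fixture(scope="session")
def settings():
    return ExperimentSettings(adduct="[M+H]+", instrument="Orbitrap", collision_energy=20.0)


@pytest.fixture
def make_mock_backend():
    def _make(**kwargs):
        kwargs.setdefault("fragment_depth", 1)
        return MockBackend(MockOracleConfig(**kwargs))

    return _make


@pytest.fixture(scope="session")
def fixture_library():
    """25 deterministic annotated spectra with mild noise and decoys."""
    return generate_fixtures(
        FixtureConfig(n_molecules=25, seed=11, fragment_depth=1, noise_sd=0.05, decoy_rate=0.1)
    )
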