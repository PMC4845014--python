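import pytest

from repmeth import (MethylomeSample, SimulationConfig, analyse_simulation,
                     write_fixture)


def make_sample(sites: dict, sample_id: str = "s") -> MethylomeSample:
    """Build a sample from {(chrom, pos): (meth, unmeth)}."""
    return MethylomeSample.from_sites(sample_id, sites)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated analysis, shared across tests."""
    return analyse_simulation(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete on-disk input fixture written by the simulator."""
    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(SimulationConfig(seed=3), directory)
    return directory
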