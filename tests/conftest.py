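import pytest

from intronreg.simulate import SimConfig, simulate_genome_pair


@pytest.fixture(scope="session")
def small_pair():
    """A 50-gene synthetic genome pair shared across tests."""
    return simulate_genome_pair(SimConfig(seed=101, n_genes=50))


@pytest.fixture(scope="session")
def small_pair_dir(small_pair, tmp_path_factory):
    """The same pair written out as a file bundle."""
    from intronreg.simulate import write_simulation

    outdir = tmp_path_factory.mktemp("simbundle")
    paths = write_simulation(small_pair, str(outdir))
    return paths
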