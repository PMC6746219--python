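import numpy as np
import pytest
from hypothesis import settings

from allosrna import SimConfig, make_genomes
from allosrna.simulate import write_libraries

settings.register_profile("repro", derandomize=True, max_examples=50,
                          deadline=None, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return SimConfig(seed=3, n_mirna_loci=5, n_sirna_loci=8, read_depth=6000,
                     chrom_len=25_000, n_transcripts=40)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    return make_genomes(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_run_dir(tiny_cfg, tiny_sim, tmp_path_factory):
    """Synthetic references + libraries on disk, shared across tests."""
    root = tmp_path_factory.mktemp("tiny_run")
    paths = tiny_sim.write(root / "ref")
    sheet = write_libraries(tiny_cfg, tiny_sim, root / "libs")
    return root, paths, sheet


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
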