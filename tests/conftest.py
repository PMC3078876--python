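import numpy as np
import pytest

from srnapipe.seqio import RefRecord
from srnapipe.simulate import SimulationConfig, generate_reference_set, sample_libraries

RNG_SEED = 20_240_101


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(RNG_SEED)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic experiment, small enough for unit tests."""
    return SimulationConfig(
        seed=11,
        n_conserved_families=6,
        n_novel_loci=2,
        fp_depth=20_000,
        sp_depth=20_000,
        n_noise_tags=500,
        n_ncrna_fragments=40,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    bundle, truth = generate_reference_set(small_config)
    libraries = sample_libraries(small_config, truth)
    return small_config, bundle, truth, libraries


@pytest.fixture
def tiny_refs():
    """Hand-built references for annotation tests."""
    ncrna = [
        RefRecord("rRNA1", "rRNA", "", "ACGTACGTAC" * 6),
        RefRecord("tRNA1", "tRNA", "", "GGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGCA"),
    ]
    mirna = [
        RefRecord("rgl-miR1a", "known_miRNA", "miR1", "TGACAGAAGAGAGTGAGCACA"),
        RefRecord("rgl-miR2a", "known_miRNA", "miR2", "TTGGACTGAAGGGAGCTCCCT"),
    ]
    genome = [("chr1", "TTTTGCATGCATGCATGCAAAACCCGGGTTTACCCTTGATTCCACGGACT" * 4)]
    return ncrna, mirna, genome
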