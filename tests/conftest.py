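import numpy as np
import pytest

from longapa.synthetic_data import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (deep enough for peak
    calling on most genes)."""
    cfg = SimConfig(n_genes=40, reads_total=16000, seed=11)
    genome, annotation, truth = simulate_genome(cfg)
    reads = simulate_reads(annotation, truth, cfg, rng=np.random.default_rng(12))
    return cfg, genome, annotation, truth, reads
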