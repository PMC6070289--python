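import numpy as np
import pytest

from uorfkit.simulate import SimulationConfig, generate_counts, generate_transcriptome
from uorfkit.te_stats import DispersionTrend


@pytest.fixture(scope="session")
def small_transcriptome():
    cfg = SimulationConfig(seed=11, n_genes=40)
    transcripts, truth = generate_transcriptome(cfg)
    return cfg, transcripts, truth


@pytest.fixture(scope="session")
def small_counts(small_transcriptome):
    cfg, transcripts, truth = small_transcriptome
    counts = generate_counts(transcripts, truth, cfg)
    return cfg, transcripts, truth, counts


@pytest.fixture
def trends():
    return (DispersionTrend("mrna", 0.05, 5.0), DispersionTrend("rpf", 0.05, 5.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
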