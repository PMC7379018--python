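import numpy as np
import pytest

from pipseq import SimulationConfig, simulate_annotation, simulate_libraries
from pipseq.genome_io import TranscriptModel


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_transcripts=40, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    annotation, truth = simulate_annotation(small_cfg)
    libraries = simulate_libraries(annotation, truth, small_cfg)
    return annotation, truth, libraries


@pytest.fixture
def toy_mrna():
    """Single-exon plus-strand mRNA chr1:100-400 with CDS 150-300."""
    return TranscriptModel("toy1", "chr1", "+", [(100, 400)], (150, 300))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
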