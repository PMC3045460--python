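import numpy as np
import pytest

from pyroest import synth
from pyroest.trim import TrimSpec


@pytest.fixture(scope="session")
def spec():
    return TrimSpec()


@pytest.fixture(scope="session")
def transcripts():
    return synth.generate_transcriptome(8, seed=11)


@pytest.fixture(scope="session")
def planted(transcripts):
    return synth.plant_variants(transcripts, seed=12)


@pytest.fixture(scope="session")
def abundances(transcripts):
    return synth.AbundanceTable.random(transcripts, n_exclusive_r=1,
                                       n_exclusive_s=1, seed=13)


@pytest.fixture(scope="session")
def simulated(transcripts, planted, abundances):
    """Moderate-size two-strain read set with planted variants, no noise."""
    return synth.simulate_reads(
        transcripts, abundances, n_reads_per_strain=2000,
        variants=planted, seed=14)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
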