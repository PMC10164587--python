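import numpy as np
import pytest

from duplexatlas.reference import TranscriptRecord
from duplexatlas.simulate import SimulationConfig, simulate_reads, simulate_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by several test modules."""
    rng = np.random.default_rng(7)
    config = SimulationConfig(
        n_transcripts=10,
        length_range=(800, 1500),
        n_duplexes=60,
        n_hairpins=10,
        pcr_duplication_rate=0.0,
    )
    records, truth = simulate_transcriptome(config, rng)
    reads = simulate_reads(records, truth, config, rng, n_reads=300)
    return config, records, truth, reads


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def toy_records():
    """Two annotated transcripts plus one unannotated."""
    return {
        "TX1": TranscriptRecord(
            "TX1",
            "G1",
            "ACGT" * 50,
            regions=[("UTR5", 0, 40), ("CDS", 40, 140), ("UTR3", 140, 200)],
        ),
        "TX2": TranscriptRecord(
            "TX2", "G2", "GGCC" * 30, regions=[("CDS", 0, 60), ("UTR3", 60, 120)]
        ),
        "TX3": TranscriptRecord("TX3", "G3", "ATAT" * 25),
    }
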