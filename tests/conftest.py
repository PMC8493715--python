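import numpy as np
import pytest

from gammarep.annotate import annotate
from gammarep.demux import demultiplex
from gammarep.reference import bundled_reference
from gammarep.simulate import (
    PublicCloneSpec,
    SimulationConfig,
    simulate_reads,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture(scope="session")
def small_sim(reference):
    """A small error-free two-tissue simulation with one fully public clone,
    run through demultiplex + annotate once and shared across tests."""
    cfg = SimulationConfig(
        seed=7,
        birds_per_line=3,
        tissues=("thymus", "spleen"),
        reads_per_sample=300,
        clones_per_bird=25,
        public_pool=(
            PublicCloneSpec("TRGV3.1", penetrance=1.0, expansion_factor=4.0,
                            j_id="TRGJ1",
                            junction_nt=None),
        ),
    )
    truth, clones = simulate_repertoire(cfg, reference)
    reads, sheet, truth_reads = simulate_reads(truth, reference, cfg)
    streams, counts = demultiplex(reads, sheet)
    airr, summary = annotate(streams, reference, sample_metadata=sheet.metadata())
    return dict(cfg=cfg, truth=truth, clones=clones, reads=reads, sheet=sheet,
                truth_reads=truth_reads, streams=streams, demux_counts=counts,
                airr=airr, summary=summary)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
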