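import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ltrscape.simulate import ElementSpec, SimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated genome shared by read-only tests: two cohorts of
    full-length elements plus genes on two contigs."""
    config = SimConfig(
        seed=11,
        n_contigs=2,
        contig_length=150_000,
        n_genes=20,
        elements=[
            ElementSpec("Gypsy", 500, 1500, 20e6, 8),
            ElementSpec("Copia", 500, 1500, 5e6, 6),
        ],
    )
    return simulate_genome(config)


@pytest.fixture
def sim_dir(small_sim, tmp_path):
    """The shared simulation written to disk (FASTA + GFF3 + truth)."""
    return small_sim.write(tmp_path / "sim")
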