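import pytest

from tagdge import SimConfig, simulate_tag_libraries, simulate_transcriptome


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=7,
        n_genes=100,
        depth_per_library=50_000,
        deg_fraction=0.1,
        log2_effect=2.0,
        error_rate=0.001,
        antisense_fraction=0.18,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Transcriptome, two read libraries and ground truth, drawn once."""
    transcripts = simulate_transcriptome(small_config)
    reads1, reads2, truth = simulate_tag_libraries(transcripts, small_config)
    return transcripts, reads1, reads2, truth


@pytest.fixture(scope="session")
def clean_config():
    """Error-free, sense-only configuration for exact bookkeeping tests."""
    return SimConfig(
        seed=11,
        n_genes=60,
        depth_per_library=20_000,
        deg_fraction=0.0,
        error_rate=0.0,
        antisense_fraction=0.0,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    transcripts = simulate_transcriptome(clean_config)
    reads1, reads2, truth = simulate_tag_libraries(transcripts, clean_config)
    return transcripts, reads1, reads2, truth
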