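import pytest

from txarch.synthetic_data import NoiseConfig, generate_genome, simulate_coverage


@pytest.fixture(scope="session")
def noiseless_dataset():
    """A 60-gene synthetic genome with exact (noise-free) coverage."""
    sequence, truth = generate_genome(60, seed=11)
    tracks = simulate_coverage(truth, noise=NoiseConfig(noiseless=True), seed=11)
    return sequence, truth, tracks
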