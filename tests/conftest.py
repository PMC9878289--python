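import pytest

from smnscreen import (
    SampleGenotype,
    SimulationParams,
    default_config,
    simulate_sample,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def params():
    """Study-condition sequencing model: depth 50 per copy, 2x150, e=0.001."""
    return SimulationParams(haploid_depth=50.0, error_rate=0.001)


@pytest.fixture(scope="session")
def clean_params():
    """Error-free variant for oracle tests."""
    return SimulationParams(haploid_depth=50.0, error_rate=0.0)


@pytest.fixture
def make_sample(cfg):
    """Simulate one sample's reads for a genotype at a given seed."""

    def _make(smn1, smn2, seed, p=None, sample_id="s"):
        p = p or SimulationParams(haploid_depth=50.0, error_rate=0.001)
        return simulate_sample(SampleGenotype(sample_id, smn1, smn2), p, cfg, seed=seed)

    return _make
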