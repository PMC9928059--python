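import pytest

from relocus import sim


@pytest.fixture(scope="session")
def default_cfg() -> sim.SyntheticConfig:
    return sim.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def fixture_full(default_cfg) -> sim.SimFixture:
    """Full default fixture (annotation, peaks, sequence, counts) at seed 0."""
    return sim.generate_fixture(default_cfg)


@pytest.fixture(scope="session")
def annotation(default_cfg):
    return sim.generate_annotation(default_cfg)
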