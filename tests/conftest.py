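import pytest

from wormfret import GeneratorConfig


@pytest.fixture
def config() -> GeneratorConfig:
    """Default study-condition generator configuration."""
    return GeneratorConfig()


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    """Generator with measurement and dispensing noise switched off."""
    return GeneratorConfig(channel_cv=0.0, dispense_cv=0.0)
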