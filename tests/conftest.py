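import pytest

from psmcea.config import evaluate_arms, load_default_config


@pytest.fixture(scope="session")
def config():
    """Shipped published-parameter fixture (Taiwan 2022 NT$, monthly cycles)."""
    return load_default_config()


@pytest.fixture(scope="session")
def base_outcomes(config):
    """Deterministic base-case outcomes for all three arms."""
    return evaluate_arms(config)
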