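import pytest

from sclcea import load_config
from sclcea.markov_engine import ModelSettings
from sclcea.workflow import build_settings, build_strategy


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def settings(cfg):
    return build_settings(cfg)


@pytest.fixture(scope="session")
def adchm(cfg):
    return build_strategy(cfg, "adchm")


@pytest.fixture(scope="session")
def plchm(cfg):
    return build_strategy(cfg, "plchm")


@pytest.fixture
def quick_settings():
    """Short-horizon settings for structural tests that don't need 120 cycles."""
    return ModelSettings(n_cycles=20)
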