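import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hrcxr.config import NetworkConfig
from hrcxr.data import SyntheticSpec, generate_synthetic_dataset
from hrcxr.train import train

# miniature architecture used throughout the CPU tests
MINI = dict(
    branch_widths=(8, 16, 32, 64), modules_per_stage=(1, 1, 1),
    blocks_per_module=1, stage1_blocks=1, stem_width=16, ca_reduction=4,
    head_hidden=(128, 64),
)


def make_mini_config(**overrides) -> NetworkConfig:
    kw = dict(MINI, num_classes=14, input_size=64)
    kw.update(overrides)
    return NetworkConfig(**kw)


@pytest.fixture
def mini_config():
    return make_mini_config()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_synthetic_run():
    """A converged miniature run on separable synthetic data (shared by the
    end-to-end learnability and heatmap-localization tests)."""
    ds = generate_synthetic_dataset(SyntheticSpec(), 2000, seed=42)
    cfg = make_mini_config()
    net, state = train(cfg, ds, max_epochs=10, batch_size=64, seed=0)
    return ds, net, state
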