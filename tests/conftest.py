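import numpy as np
import pytest

from lapseg.network import MultiScaleAttentionNet, NetworkConfig
from lapseg.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    """Small network for fast forward/backward tests."""
    return NetworkConfig(num_classes=4, base_width=8, backbone_depth=1,
                         fused_channels=16, channel_reduction_ratio=4,
                         init_seed=42)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg) -> MultiScaleAttentionNet:
    return MultiScaleAttentionNet(tiny_cfg)


@pytest.fixture(scope="session")
def scene_pair():
    """One default-conditions 64x64 scene."""
    return generate_scene(SceneSpec(seed=11), 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
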