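import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_model():
    """Width-8 contour model shared by read-only forward-pass tests."""
    from echostrain.head import ContourModel
    from echostrain.swin import TOY_CONFIG

    return ContourModel(TOY_CONFIG)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest valid architecture, for fast training-loop tests."""
    from echostrain.swin import ModelConfig

    return ModelConfig(embed_dim=4, depths=(2, 2, 2), heads=(1, 1, 2),
                       fusion_dim=8, output_scale=32.0)


@pytest.fixture(scope="session")
def phantom_video():
    """One deterministic speckled phantom clip with all ground truths."""
    from echostrain.phantom import PhantomConfig, make_phantom_video

    cfg = PhantomConfig(n_cycles=1, seed=7)
    fs, cs, masks, truth = make_phantom_video(cfg)
    return cfg, fs, cs, masks, truth


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (for finite-difference checks)."""
    from echostrain import nn

    nn.set_dtype(np.float64)
    yield
    nn.set_dtype(np.float32)
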