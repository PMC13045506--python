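import numpy as np
import pytest
from hypothesis import settings

from wheatstage.backbone import FeaturePyramid, WIDTH_PRESETS
from wheatstage.model import ModelConfig, build_model
from wheatstage.nn import Tensor

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def reference_model():
    """Full-width fusion model, built once (used by audit and shape tests)."""
    return build_model(ModelConfig(variant="amsaf", width_preset="reference",
                                   seed=0)).eval()


@pytest.fixture(scope="session")
def tiny_model():
    """Tiny-width fusion model for 64x64 inputs (read-only across tests)."""
    return build_model(ModelConfig(variant="amsaf", width_preset="tiny",
                                   seed=0), input_size=64).eval()


def make_pyramid(batch: int, preset: str, input_hw: int,
                 rng: np.random.Generator) -> FeaturePyramid:
    """Random feature pyramid with the preset's channel/spatial layout."""
    stages = WIDTH_PRESETS[preset]["stages"]
    feats = [
        Tensor(rng.random((batch, c, input_hw // s, input_hw // s),
                          dtype=np.float32))
        for c, s in zip(stages, (4, 8, 16, 32))
    ]
    return FeaturePyramid(*feats)
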