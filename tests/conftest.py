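import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from qfusion import FusionConfig, FusionModel


TOY = dict(dA=6, dB=5, P=8, r=3, n_heads=2, hidden_dim=7, n_classes=5,
           dropout_rate=0.0)


@pytest.fixture
def toy_model():
    """A small fusion model with dropout off (deterministic inference)."""
    return FusionModel(FusionConfig(**TOY, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
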