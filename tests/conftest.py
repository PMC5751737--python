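import numpy as np
import pytest

from mangosize.detection import DetectorConfig, train_detector
from mangosize.synthetic import default_scene_intrinsics, make_training_snips


@pytest.fixture(scope="session")
def scene_intrinsics():
    return default_scene_intrinsics()


@pytest.fixture(scope="session")
def detector():
    """One cascade trained on generator snips, shared across the session."""
    pos, neg = make_training_snips(400, 400, seed=7)
    return train_detector(pos, neg, DetectorConfig(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
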