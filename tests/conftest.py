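import numpy as np
import pytest

from powerhazard import CensoringScheme, PHFDParams, ProgCensSample
from powerhazard.datasets import BALL_BEARING_BETA, ball_bearing_sample

BETA = BALL_BEARING_BETA  # 0.332, the shape used throughout worked examples


@pytest.fixture(scope="session")
def bearings() -> ProgCensSample:
    """Censored ball-bearing dataset: n=23, m=18."""
    return ball_bearing_sample()


@pytest.fixture
def params() -> PHFDParams:
    return PHFDParams(alpha=1.1835, beta=BETA)


@pytest.fixture
def toy_sample() -> ProgCensSample:
    """Tiny hand-checkable sample: n=8, m=5."""
    scheme = CensoringScheme(n=8, removals=(1, 0, 2, 0, 0))
    return ProgCensSample(scheme=scheme, times=(0.3, 0.7, 1.1, 1.6, 2.4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260904)
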