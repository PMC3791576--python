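import numpy as np
import pytest

from chromval.calibration import fit_calibration
from chromval.synth import ResponseModel


@pytest.fixture
def noise_free_model() -> ResponseModel:
    return ResponseModel(noise_rsd_by_level={}, seed=0)


@pytest.fixture
def default_model() -> ResponseModel:
    return ResponseModel(seed=123)


@pytest.fixture
def toy_fit():
    """Fixed 3-point calibration used by the hand-evaluated inverse-prediction oracle."""
    return fit_calibration([1.0, 2.0, 3.0], [2.1, 3.9, 6.1])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
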