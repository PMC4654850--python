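import numpy as np
import pytest

from eyespot.geometry import EyeModel, ViewTransform


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_sphere_eye():
    return EyeModel((1.0, 1.0, 1.0), 53.0)


@pytest.fixture
def ellipsoid_eye():
    return EyeModel((1.3, 1.0, 1.1), 53.0)


@pytest.fixture
def identity_view():
    return ViewTransform((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), "top")
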