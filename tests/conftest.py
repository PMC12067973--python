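import numpy as np
import pytest

from flashchem.beam import PulseStructure, ROIGeometry


@pytest.fixture
def roi_small() -> ROIGeometry:
    """Sub-micron periodic box for fast chemistry tests."""
    return ROIGeometry(face_side_um=0.1, depth_um=0.1)


@pytest.fixture
def pulse() -> PulseStructure:
    return PulseStructure()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
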