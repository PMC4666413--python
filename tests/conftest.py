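import numpy as np
import pytest

from pvsquant.roi_tools import RoiMask, make_ovoid_roi
from pvsquant.synthetic import default_roi_spec


@pytest.fixture(scope="session")
def default_roi() -> RoiMask:
    """Bilateral ovoid BG ROI matching the default phantom geometry."""
    return make_ovoid_roi((256, 256), default_roi_spec())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
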