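import logging

import numpy as np
import pytest

from repsurv import FeatureConfig, gen_phantom_study
from repsurv.texture import LabeledStudy

# keep expected-failure log chatter (missing regions, degenerate inputs)
# out of the test output
logging.getLogger("repsurv").setLevel(logging.ERROR)


SMALL_SEMI_AXES = {
    "edema": (14.0, 12.0, 10.0),
    "enhancing": (9.0, 7.5, 6.0),
    "necrosis": (5.0, 4.0, 3.5),
}


@pytest.fixture(scope="session")
def phantom():
    """A 40^3 textured phantom reused across feature tests."""
    return gen_phantom_study(
        semi_axes=SMALL_SEMI_AXES,
        region_hurst={"edema": 0.6, "enhancing": 0.4, "necrosis": 0.5},
        noise_sd=1.0,
        seed=11,
        size=40,
    )


@pytest.fixture(scope="session")
def phantom_study(phantom):
    return LabeledStudy(
        intensity=phantom.intensity,
        labels=phantom.labels,
        spacing=phantom.spacing,
        subject_id="PH000",
        brain_mask=phantom.brain_mask(),
    )


@pytest.fixture(scope="session")
def small_feature_config():
    return FeatureConfig(ptpsa_window=4, ptpsa_scales=(1, 2, 4), holder_radius=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
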