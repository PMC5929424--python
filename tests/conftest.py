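import logging

import numpy as np
import pytest

from thyquant import RunConfig
from thyquant.synthetic import SynthParams, generate_tissue

# empty-subROI warnings are routine for SURS tiles landing in stroma
logging.getLogger("thyquant.quantitation").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    """Desk-scale slide: seven mid-sized follicles in a 512 px frame."""
    return SynthParams(
        image_width_px=512,
        image_height_px=512,
        n_follicles=7,
        follicle_radius_um=(40.0, 80.0),
        dab_positive_fraction=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_case(small_params):
    return generate_tissue(small_params)


@pytest.fixture(scope="session")
def fullroi_config() -> RunConfig:
    """Quantify the entire frame (SURS at fraction 1 keeps every tile)."""
    return RunConfig(mpp=1.0, sampling_method="surs", surs_fraction=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * float(np.sum(a & b)) / denom if denom else 1.0
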