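import numpy as np
import pytest

from fernmask.synthetic import SheetConfig, generate_sheet


@pytest.fixture(scope="session")
def default_sheets():
    """20 default-config synthetic sheets (all elements on)."""
    return [generate_sheet(SheetConfig(seed=s)) for s in range(20)]


@pytest.fixture(scope="session")
def clean_sheets():
    """20 element-free, debris-free sheets (plant on bare paper)."""
    return [generate_sheet(SheetConfig(seed=s).without_elements()) for s in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8)):
    return np.where(rng.random(shape) < 0.5, 255, 0).astype(np.uint8)
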