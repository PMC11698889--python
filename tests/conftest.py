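import numpy as np
import pytest

from lamap.imaging import AcquisitionMeta, ElementImage
from lamap.synthetic import PhantomConfig


@pytest.fixture
def meta():
    return AcquisitionMeta(isotopes=["56Fe", "63Cu", "88Sr"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Compact phantom for fast end-to-end tests."""
    return PhantomConfig(shape=(60, 80), seed=0)


def make_image(data, isotope="56Fe"):
    data = np.asarray(data, dtype=float)
    return ElementImage(isotope, data, AcquisitionMeta(isotopes=[isotope]))
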