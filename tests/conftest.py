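import numpy as np
import pytest

from beefmetrics.phantoms import (
    SteakPhantomSpec,
    USPhantomSpec,
    generate_steak_phantom,
    generate_us_phantom,
)


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Jaccard overlap of two boolean masks (test-local oracle)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 1.0 - np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


@pytest.fixture(scope="session")
def steak_phantom():
    """Default steak phantom: constant 20 px backfat band, seed 0."""
    return generate_steak_phantom(SteakPhantomSpec())


@pytest.fixture(scope="session")
def steak_phantom_ramp():
    """Steak phantom with a 10 -> 30 px backfat thickness ramp."""
    return generate_steak_phantom(SteakPhantomSpec(band_thickness=(10.0, 30.0)))


@pytest.fixture(scope="session")
def us_phantom():
    return generate_us_phantom(USPhantomSpec())
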