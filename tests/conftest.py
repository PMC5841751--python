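import numpy as np
import pytest
from hypothesis import settings

from ntra import (
    NTRAParameters,
    PixelSet,
    build_histogram,
    smooth_histogram,
)
from ntra.cohort import sample_mixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def known_params() -> NTRAParameters:
    """A realistic trimodal ground truth used across fitting tests."""
    return NTRAParameters(
        N=np.array([0.3, 0.15, 0.55]),
        mu=np.array([-60.0, 10.0, 52.0]),
        sigma=np.array([25.0, 12.0, 14.0]),
        alpha=np.array([-2.0, 0.0, 1.5]),
    )


@pytest.fixture(scope="session")
def trimodal_pixels(known_params) -> PixelSet:
    """1e5 pixels sampled from the known trimodal model."""
    rng = np.random.default_rng(42)
    values = sample_mixture(100_000, known_params, rng)
    return PixelSet(subject_id="fixture", values=values, unit="hounsfield")


@pytest.fixture(scope="session")
def trimodal_hist(trimodal_pixels):
    """Smoothed 128-bin histogram of the fixture pixels."""
    return smooth_histogram(build_histogram(trimodal_pixels))
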