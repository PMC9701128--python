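"""Shared fixtures: synthetic samples and pipeline products.

Session-scoped so expensive pipeline stages run once and are reused across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemseg.synth import SynthConfig, generate_sample
from hemseg.preprocess import preprocess_image, green_channel
from hemseg.seeds import extract_seed_points
from hemseg.calibrate import calibrate
from hemseg.swat import segment_all

PIPELINE_SIGMAS = (6.0, 12.0)
PIPELINE_SEED_PAD = 12


@pytest.fixture(scope="session")
def sample():
    """One default-condition synthetic fundus sample."""
    return generate_sample(SynthConfig(rng_seed=7))


@pytest.fixture(scope="session")
def enhanced(sample):
    return preprocess_image(sample.image)


@pytest.fixture(scope="session")
def products(sample, enhanced):
    return calibrate(enhanced, green_raw=green_channel(sample.image))


@pytest.fixture(scope="session")
def seeds(products):
    return extract_seed_points(products.calibrated_image, sigmas=PIPELINE_SIGMAS)


@pytest.fixture(scope="session")
def candidates(products, seeds):
    return segment_all(
        products.calibrated_image, seeds, products.search_space,
        seed_pad=PIPELINE_SEED_PAD,
    )


def make_disc(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
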