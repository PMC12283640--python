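import numpy as np
import pytest

from plaquecam import (
    CANVAS_SHAPE,
    BandOracleModel,
    GeneratorConfig,
    StandardizedImage,
    render_phantom,
    sample_phantom_spec,
    standardize_sample,
)


def make_standardized(pixels=None, plaque_mask=None) -> StandardizedImage:
    """Canvas-shaped standardized image for toy constructions."""
    if pixels is None:
        pixels = np.zeros(CANVAS_SHAPE, dtype=np.uint8)
    if plaque_mask is None:
        plaque_mask = np.ones(CANVAS_SHAPE, dtype=bool)
    return StandardizedImage(pixels, plaque_mask)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def sy_phantom():
    return render_phantom(sample_phantom_spec("SY", rng_seed=11))


@pytest.fixture(scope="session")
def sy_standardized(sy_phantom):
    std, (truth,) = standardize_sample(
        sy_phantom.image,
        sy_phantom.plaque_mask,
        sy_phantom.refs,
        extra_masks=(sy_phantom.composition_truth,),
    )
    return std, truth


@pytest.fixture(scope="session")
def bk_oracle():
    return BandOracleModel("bk", attend_class="SY")
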