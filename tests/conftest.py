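import numpy as np
import pytest

from frn3d import BackboneConfig, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_backbone_cfg():
    """Narrow four-block extractor for fast CPU tests (16^3 -> 1^3 grid is
    avoided: strides leave a 2^3 grid at 16^3 input)."""
    return BackboneConfig(block_channels=(2, 4, 4, 8),
                          downsample_per_block=(True, True, True, False))


@pytest.fixture(scope="session")
def toy_backbone_cfg():
    """The configuration used for the small end-to-end studies (32^3 input)."""
    return BackboneConfig(block_channels=(4, 8, 8, 16),
                          downsample_per_block=(True, True, True, True))


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-subject cohort of 16^3 volumes with a strong localized effect."""
    cfg = SyntheticConfig(shape=(16, 16, 16), n_per_class=6, effect_size=4.0,
                          n_effect_regions=2, region_radius_vox=3,
                          smoothness_fwhm_vox=4.0, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
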