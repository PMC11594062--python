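import numpy as np
import pytest

from neurohcs.model import SiteIds, SiteImage, default_channel_map
from neurohcs.experiments import small_scene
from neurohcs.synth import generate_site_image


@pytest.fixture
def drebrin_map():
    return default_channel_map("drebrin")


@pytest.fixture
def noiseless_scene():
    return small_scene(noisy=False)


@pytest.fixture
def noisy_scene():
    return small_scene(noisy=True)


@pytest.fixture
def noiseless_site(noiseless_scene, drebrin_map):
    """One deterministic zero-noise synthetic site plus its ground truth."""
    return generate_site_image(noiseless_scene, drebrin_map, seed=11)


@pytest.fixture
def noisy_site(noisy_scene, drebrin_map):
    return generate_site_image(noisy_scene, drebrin_map, seed=11)


def make_image(pixels, channel_map=None, **ids):
    """Wrap a raw (C, H, W) uint16 array into a SiteImage."""
    channel_map = channel_map or default_channel_map("drebrin")
    defaults = dict(culture="c1", group="vehicle", well=0, site=0)
    defaults.update(ids)
    return SiteImage(np.asarray(pixels, dtype=np.uint16), channel_map,
                     SiteIds(**defaults))


@pytest.fixture
def image_factory():
    return make_image
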