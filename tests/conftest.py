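import numpy as np
import pytest

import erovox as ev
from erovox import presets


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_phantom():
    """128³ phantom with three erosions, one channel and an osteophyte
    pair; shared across detection/measurement tests."""
    spec = ev.PhantomSpec(
        shape=(128, 128, 128), spacing=(0.0607,) * 3,
        semi_axes_mm=(2.6, 2.6, 2.6), exponent=4.0, cortical_thickness_mm=1.8,
        erosions=[ev.ErosionSpec((1, 0, 0), 0.8),
                  ev.ErosionSpec((0, 1, 0), 1.0),
                  ev.ErosionSpec((-1, 0, 0), 1.2)],
        channels=[ev.ChannelSpec((0, 0, -1), 0.2, 1.0)],
        osteophytes=ev.osteophyte_pair(
            (0, 0, 1), separation_mm=2.0, tangent=(1, 0, 0),
            height_mm=0.9, radius_mm=0.7,
            semi_axes_mm=(2.6, 2.6, 2.6), exponent=4.0),
        noise_sd=50.0, seed=3)
    vol, truth = ev.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_detection(small_phantom):
    spec, vol, truth = small_phantom
    cfg = ev.DetectionConfig(closing_radius_mm=4.8)
    return vol, truth, cfg, ev.detect_erosions(vol, cfg)


@pytest.fixture(scope="session")
def mch_detection():
    """The full-scale reference phantom detection (also used by the
    acceptance tests)."""
    spec = presets.mch_phantom(seed=11)
    vol, truth = ev.generate_phantom(spec)
    cfg = presets.mch_config()
    return vol, truth, cfg, ev.detect_erosions(vol, cfg)
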