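import numpy as np
import pytest

from petloop import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def label_map():
    return phantom.make_label_map((32, 32, 32))


@pytest.fixture(scope="session")
def disc_scene():
    """Zero-noise two-color disc scene with its ground-truth mask."""
    spec = phantom.SceneSpec(shape=(48, 48), center=(24.0, 24.0), radius=9.0)
    img, mask = phantom.make_color_scene(spec)
    return spec, img, mask


def random_tac_params(rng, peak_time=60.0):
    peak = rng.uniform(1.0, 3.0)
    start = rng.uniform(0.0, peak)
    end = rng.uniform(0.0, peak)
    return phantom.TacParams(start, peak, peak_time, end)


def random_roi_params(rng, peak_times=(15.0, 60.0, 135.0)):
    return {
        key: random_tac_params(rng, peak_time=rng.choice(peak_times))
        for key in phantom.LOOP_ROI_KEYS
    }
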