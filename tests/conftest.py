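import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

from svdose import synthetic_data as synth


@pytest.fixture(scope="session")
def small_spec():
    """A miniature acquisition geometry for fast unit tests.

    40 slow-axis lines give two surface-contour knots (0 and 20); four
    repetitions keep rendering cheap.
    """
    return synth.CohortSpec(seed=7, raw_shape=(48, 40, 4, 32))


@pytest.fixture(scope="session")
def small_acquisition(small_spec):
    """One rendered low-dose acquisition plus its ground truth."""
    net = synth.generate_vessel_network(small_spec, "low", 17, 11)
    raw, gt = synth.render_acquisition(
        net, small_spec, 12, mouse_id="L1", day=17, dose_class="low"
    )
    return net, raw, gt


def make_volume(mouse_id, dose_class, day, shape=(8, 8, 8), seed=0, tag="original"):
    from svdose.dataset import LabeledVolume

    rng = np.random.default_rng(seed)
    return LabeledVolume(
        volume=rng.uniform(size=shape).astype(np.float32),
        dose_class=dose_class,
        mouse_id=mouse_id,
        day=day,
        augmentation=tag,
    )
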