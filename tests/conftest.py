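import numpy as np
import pytest

from sheepvitals.synthetic import SceneSpec, generate_rgb_scene
from sheepvitals.video import TrackedROI, crop_stack
from sheepvitals.signals import extract_series


def make_scene(**kw):
    """A small, quick default scene spec for unit tests."""
    defaults = dict(width=48, height=36, roi_true=(14, 9, 20, 16),
                    n_frames=900, fps=30.0, seed=11)
    defaults.update(kw)
    return SceneSpec(**defaults)


def scene_series(spec, channel):
    """Generate a scene and extract one channel series from the true ROI."""
    stack, truth = generate_rgb_scene(spec)
    crop = crop_stack(stack, TrackedROI.static(spec.roi_true, spec.n_frames))
    return extract_series(crop, channel), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
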