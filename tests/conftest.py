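import numpy as np
import pytest

from aortacad.circle import PairTolerances
from aortacad.gradients import sobel_field
from aortacad.phantom import PhantomSpec, make_healthy_slice
from aortacad.segmentation import label_components, threshold_lumen
from aortacad.types import HURange


@pytest.fixture
def lumen_range():
    return HURange(200, 500)


@pytest.fixture
def default_tol():
    return PairTolerances()


@pytest.fixture
def disk20():
    """Noise-free radius-20 phantom disk: (slice, truth mask, object, field)."""
    spec = PhantomSpec(radius=20)
    ct, truth = make_healthy_slice(spec, 0)
    obj = label_components(threshold_lumen(ct, spec.hu_range), min_size=50)[0]
    return ct, truth, obj, sobel_field(ct)


def random_blob(rng, shape=(64, 64), max_boundary=200):
    """A random smooth blob image for oracle-equivalence checks.

    Returns (slice pixels as HU, blob object) with the blob at lumen-like
    intensity, or None when the draw has no usable component.
    """
    from scipy import ndimage

    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=rng.uniform(4.0, 8.0))
    mask = smooth > np.quantile(smooth, 0.85)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return None
    sizes = ndimage.sum(mask, labeled, range(1, n + 1))
    blob = labeled == (1 + int(np.argmax(sizes)))
    if blob.sum() < 60:
        return None
    img = np.full(shape, 40, dtype=np.int32)
    img[blob] = 350
    return img, blob
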