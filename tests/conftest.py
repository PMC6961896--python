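import numpy as np
import pytest

from usradiomics.imaging import QuantizedPatch, RoiPatch


def qpatch(levels_array, levels=None, mask=None):
    """QuantizedPatch from a small integer array (0 = outside the ROI)."""
    arr = np.asarray(levels_array, dtype=np.int64)
    if mask is None:
        mask = arr > 0
    if levels is None:
        levels = max(2, int(arr.max()))
    return QuantizedPatch(arr, mask, levels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def speckle_patch(rng):
    """A normalized ROI patch from one synthetic speckle image."""
    from usradiomics.imaging import extract_roi, normalize_patch
    from usradiomics.synthetic import SyntheticConfig, generate_image

    pat = generate_image(SyntheticConfig(image_size=(64, 64)), label=1, rng=rng)
    return normalize_patch(extract_roi(pat.image, pat.mask))
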