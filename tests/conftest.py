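import numpy as np
import pytest

from ihcquant import DiameterRange, SynthParams, render_scene


NUCLEUS_RANGE = DiameterRange(14.0, 26.0)
# The RDA HIGH channel detects eroded nucleus cores (the distance-transform
# threshold deliberately shrinks blobs to break necks), so its gate only
# needs to reject speckle at the bottom and debris at the top.
CORE_RANGE = DiameterRange(2.0, 1.5 * 26.0)


@pytest.fixture(scope="session")
def standard_scene():
    """The 30-nucleus reference scene (10 per staining level, seed 1)."""
    return render_scene(SynthParams(seed=1))


@pytest.fixture(scope="session")
def dark_scene():
    """20 well-separated strongly stained nuclei only (seed 1)."""
    return render_scene(SynthParams(seed=1, n_high=20, n_low=0, n_none=0))


def disc_mask(shape, cx, cy, r):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return np.where((xs - cx) ** 2 + (ys - cy) ** 2 <= r * r, 255, 0).astype(np.uint8)
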