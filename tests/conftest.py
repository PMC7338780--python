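import numpy as np
import pytest

from pollencount import SceneParams, generate_scene


def disc_mask(shape, center, radius):
    """Rasterized disc: pixels whose centres lie within the radius."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def small_scene():
    """A quick-to-process 640x480 scene: 18 viable + 7 non-viable grains."""
    params = SceneParams(
        width=640, height=480, n_viable=18, n_nonviable=7, seed=101
    )
    return generate_scene(params)
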