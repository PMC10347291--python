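import numpy as np
import pytest

from ricemap import Grid, GridTransform
from ricemap.synthetic import SceneConfig, generate_scene


def make_grid(values, pixel_size=10.0, origin=(0.0, None), crs="EPSG:32648", nodata=None):
    """Grid helper: origin defaults to (0, nrows*pixel) so pixel (0,0) sits at top-left."""
    values = np.asarray(values)
    north = origin[1] if origin[1] is not None else values.shape[0] * pixel_size
    t = GridTransform.from_origin(origin[0], north, pixel_size)
    return Grid(values=values, transform=t, crs=crs, nodata=nodata)


@pytest.fixture(scope="session")
def scene():
    """Default study-conditions scene, fixed seed."""
    return generate_scene(SceneConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_scene():
    return generate_scene(SceneConfig(seed=0, noise_sd=0.0, scatter_fraction=0.0))
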