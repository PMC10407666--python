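import numpy as np
import pytest

from ecostab.raster import Affine, RasterGrid, RasterStack
from ecostab.synth import SceneConfig, generate_scene


@pytest.fixture
def unit_transform():
    """1-unit pixels anchored at the origin, north-up."""
    return Affine.from_origin(0.0, 0.0, 1.0, 1.0)


def make_grid(values, transform=None, crs="EPSG:32646", nodata=None):
    transform = transform or Affine.from_origin(0.0, 0.0, 1.0, 1.0)
    return RasterGrid(np.asarray(values), transform, crs, nodata=nodata)


def make_stack(arrays, labels, transform=None, crs="EPSG:32646", nodata=None):
    return RasterStack(
        [make_grid(a, transform=transform, crs=crs, nodata=nodata) for a in arrays],
        list(labels),
    )


@pytest.fixture(scope="session")
def demo_scene():
    """Small canonical scene shared by the integration-style tests."""
    return generate_scene(SceneConfig(shape=(60, 60)), seed=11)


@pytest.fixture(scope="session")
def demo_scene_dir(tmp_path_factory, demo_scene):
    from ecostab.synth import write_scene

    out = tmp_path_factory.mktemp("scene")
    return write_scene(demo_scene, out)
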