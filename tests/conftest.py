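import numpy as np
import pytest

from ecogforward.images import ImageGrid, MaskImage
from ecogforward.phantom import SpherePhantomSpec, make_sphere_phantom
from ecogforward.surface import marching_cubes


@pytest.fixture(scope="session")
def sphere10():
    """Radius-10 mm sphere phantom on a 1 mm grid: labels, mask, surface."""
    spec = SpherePhantomSpec((10.0,), (1,), (32, 32, 32), (1.0, 1.0, 1.0))
    labels = make_sphere_phantom(spec)
    mask = MaskImage(labels.grid, labels.values > 0)
    surf = marching_cubes(mask)
    return {"spec": spec, "labels": labels, "mask": mask, "surface": surf,
            "center": spec.sphere_center()}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
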