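import numpy as np
import pytest

from cytoarch.model import Filament, MembraneModel, SceneFrame


@pytest.fixture
def vm_plane():
    """VM as the z=0 tomogram XY plane."""
    return MembraneModel.xy_plane("vm", 0.0)


@pytest.fixture
def frame():
    return SceneFrame(voxel_size_nm=(1.34, 1.34, 1.34), dims_voxels=(750, 750, 200))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def straight_filament(fid="f0", kind="actin", start=(0, 0, 0), direction=(1, 0, 0),
                      length=60.0):
    start = np.asarray(start, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    return Filament(id=fid, kind=kind,
                    points=np.vstack([start, start + direction * length]))


def random_polyline(rng, n_pts=5, scale=100.0):
    """A random jagged polyline with distinct consecutive points."""
    while True:
        pts = rng.uniform(0, scale, (n_pts, 3))
        if np.all(np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-6):
            return pts
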