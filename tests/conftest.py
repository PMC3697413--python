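import numpy as np
import pytest

from warpstrain.imaging import Image3D
from warpstrain.lvmesh import HexMesh, build_lv_mesh
from warpstrain.phantom import PhantomSpec, make_phantom_pair, render_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    """Default desk-scale phantom: (template, target, truth table, mesh)."""
    return make_phantom_pair(default_spec)


@pytest.fixture(scope="session")
def phantom_template(default_spec):
    return render_image(default_spec)


@pytest.fixture(scope="session")
def small_mesh():
    """A cheap LV mesh for assembly-level tests."""
    return build_lv_mesh(divisions=(8, 2, 2))


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """A single unit-cube hexahedron."""
    coords = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    return HexMesh(
        node_coords=coords,
        elements=np.arange(8)[None, :],
        wall_depth=np.zeros(8),
        region=np.array(["anterior"], dtype=object),
        slice_index=np.zeros(1, dtype=int),
        divisions=(1, 1, 1),
    )


def displacement_clear_of_cell_faces(img, mesh, u, h, margin_steps=25):
    """Shift a displacement field until no deformed Gauss point sits within
    ``margin_steps * h`` of a voxel-cell face.

    The trilinear image gradient is discontinuous across cell faces, so a
    finite-difference check of the image energy must keep its probe points
    strictly inside cells.
    """
    from warpstrain.lvmesh import gauss_points, shape_functions

    N = shape_functions(gauss_points())
    Xgp = mesh.gauss_coords()
    margin = margin_steps * h / img.spacing.min()
    for k in range(60):
        uk = u + 0.00137 * k
        pts = Xgp + np.einsum("ga,eax->egx", N, uk[mesh.elements])
        frac = (pts.reshape(-1, 3) - img.origin) / img.spacing
        dist = np.abs(frac - np.round(frac)).min()
        if dist > margin:
            return uk
    raise RuntimeError("could not place Gauss points away from cell faces")


@pytest.fixture
def smooth_image(rng):
    """A smooth synthetic volume for interpolation/gradient tests."""
    n = 24
    x, y, z = np.meshgrid(
        np.linspace(0, 2, n), np.linspace(0, 2, n), np.linspace(0, 2, 12),
        indexing="ij",
    )
    vox = np.sin(1.3 * x) * np.cos(0.9 * y) + 0.5 * z**2 + 0.2 * x * y * z
    return Image3D(vox, spacing=(1.5, 1.5, 3.5), origin=(-10.0, -12.0, -5.0))
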