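import numpy as np
import pytest

from corticarta import generate_atlases, generate_sheet
from corticarta.mesh import CorticalSheet


@pytest.fixture(scope="session")
def small_sheet():
    """Two-hemisphere sheet at the coarsest useful resolution (162/hemi)."""
    return generate_sheet(n_vertices=162, folding_amplitude=2.0, seed=0)


@pytest.fixture(scope="session")
def medium_sheet():
    """642 vertices per hemisphere; used where patch counts matter."""
    return generate_sheet(n_vertices=642, folding_amplitude=2.0, seed=1)


@pytest.fixture(scope="session")
def small_atlases(small_sheet):
    return generate_atlases(small_sheet, n_parcels=40, dmn_fraction=0.3, seed=2)


@pytest.fixture()
def planar_sheet():
    """Flat square sheet (identical outer/inner areas) for equidistant limits.

    Sphere coordinates are synthetic placeholders (unit vectors); spin-related
    operations are not meaningful on this fixture.
    """
    n = 8
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    outer = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, 2.0)])
    inner = outer.copy()
    inner[:, 2] = 0.0
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            faces.append([idx[i, j], idx[i + 1, j], idx[i, j + 1]])
            faces.append([idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]])
    sphere = np.zeros((n * n, 3))
    sphere[:, 2] = 1.0
    return CorticalSheet(
        outer_vertices=outer,
        inner_vertices=inner,
        faces=np.asarray(faces),
        sphere_coordinates=sphere,
        hemisphere=np.full(n * n, "L"),
    )
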