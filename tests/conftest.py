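import numpy as np
import pytest

from implantsim.arrays import make_flat_grid, place_tangential
from implantsim.gridfit import fit_to_surface
from implantsim.surface import SeedPoint, SurfaceMesh, generate_synthetic_pial


@pytest.fixture(scope="session")
def sphere70():
    """Radius-70 mm icosphere (2562 vertices) used as a synthetic envelope."""
    return generate_synthetic_pial("sphere", radius_mm=70.0, subdivisions=4)


@pytest.fixture(scope="session")
def sphere_seed(sphere70):
    return SeedPoint(
        position=sphere70.vertices[10], curvature_class="Low", vertex_index=10
    )


@pytest.fixture(scope="session")
def coarse_sphere():
    """Small sphere (320 faces) for brute-force geometry oracles."""
    return generate_synthetic_pial("sphere", radius_mm=50.0, subdivisions=2)


@pytest.fixture(scope="session")
def plane_mesh():
    """Large planar patch (z = 0) as a degenerate 'already flat' envelope."""
    vertices = np.array(
        [[-200.0, -200.0, 0.0], [200.0, -200.0, 0.0],
         [200.0, 200.0, 0.0], [-200.0, 200.0, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(vertices, faces)


@pytest.fixture(scope="session")
def fitted_4x4(sphere70, sphere_seed):
    model = make_flat_grid(4, 4, 10.0)
    init = place_tangential(model, sphere70, sphere_seed, 0.0)
    return fit_to_surface(init, model, sphere70)


@pytest.fixture(scope="session")
def fitted_8x8(sphere70, sphere_seed):
    model = make_flat_grid(8, 8, 10.0)
    init = place_tangential(model, sphere70, sphere_seed, 0.0)
    return fit_to_surface(init, model, sphere70)
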