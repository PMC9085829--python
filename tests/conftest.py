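import numpy as np
import pytest
import trimesh

from glomorph.types import SurfaceMesh
from glomorph.presets import reduced_cohort_spec, reduced_pipeline_config
from glomorph.synthetic import PhantomSpec, generate_kidney_phantom


def to_surface_mesh(tm: trimesh.Trimesh) -> SurfaceMesh:
    """Adopt a trimesh object (x, y, z) into the package's (z, y, x) frame."""
    m = SurfaceMesh(np.asarray(tm.vertices)[:, ::-1], np.asarray(tm.faces, dtype=np.int64))
    m.closed = m.is_watertight()
    return m


@pytest.fixture(scope="session")
def icosphere_r10() -> SurfaceMesh:
    """Icosphere of radius 10 µm, 3 subdivisions (analytic volume 4188.79)."""
    return to_surface_mesh(trimesh.creation.icosphere(subdivisions=3, radius=10.0))


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    return to_surface_mesh(trimesh.creation.box(extents=(1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def sphere_on_neck():
    """Full-scale single sphere head (r=35) on a cylindrical neck (r=8).

    1 µm in-plane / 4 µm z sampling; ground truth: volume 179 594 µm³,
    hMax 70 µm, nMax 16 µm.
    """
    spec = PhantomSpec(
        grid_shape=(40, 128, 128), voxel_size=(4.0, 1.0, 1.0), n_glomeruli=1,
        head_semi_axes_dist=(35.0, 0.0), neck_radius_dist=(8.0, 0.0),
        neck_length_dist=(40.0, 0.0), vessel_density=0.0, seed=3,
    )
    return generate_kidney_phantom(spec)


@pytest.fixture(scope="session")
def reduced_spec():
    return reduced_cohort_spec()


@pytest.fixture(scope="session")
def reduced_config():
    return reduced_pipeline_config()
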