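import numpy as np
import pytest

from amygshape import meshes


@pytest.fixture(scope="session")
def ico3():
    return meshes.icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return meshes.icosphere(4)


@pytest.fixture(scope="session")
def ellipsoid211(ico3):
    return meshes.as_mesh(ico3.vertices * np.array([2.0, 1.0, 1.0]), ico3.faces)


@pytest.fixture(scope="session")
def unit_cube():
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return meshes.as_mesh(box.vertices, box.faces)
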