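import numpy as np
import pytest
import trimesh

from cortexfuse import PhantomSpec, SurfacePair, TriangleMesh, generate_phantom


def icosphere(subdivisions=2, radius=30.0, center=(0.0, 0.0, 0.0)):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(ico.vertices, dtype=float) + np.asarray(center)
    return TriangleMesh(v, np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def sphere_mesh():
    return icosphere(subdivisions=2, radius=30.0)


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres 30 mm / 33 mm: uniform 3 mm thickness."""
    inner = icosphere(subdivisions=2, radius=30.0)
    outer = icosphere(subdivisions=2, radius=33.0)
    return SurfacePair(inner, outer)


@pytest.fixture(scope="session")
def phantom_subject():
    """Default synthetic subject (3 mm cortex, uptake 1.2, 64^3 grid)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def uniform_phantom():
    """Noise-free uniform phantom: thickness 3 mm, uptake 1.0 everywhere."""
    return generate_phantom(PhantomSpec(thickness=3.0, uptake=1.0,
                                        noise_sd=0.0, seed=3))
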