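import math

import numpy as np
import pytest

from sasmorph import experiments, synthgen
from sasmorph.meshing import annulus_mesh, cap_surface_mesh, disc_mesh
from sasmorph.sas_morpho import SASMesh


@pytest.fixture(scope="session")
def disc() -> SASMesh:
    """Flat triangulated disc, radius 200 nm."""
    v, f = disc_mesh(200.0)
    return SASMesh(vertices=v, triangles=f)


@pytest.fixture(scope="session")
def annulus() -> SASMesh:
    """Flat annulus (one perforation), radii 50 / 150 nm."""
    v, f = annulus_mesh(50.0, 150.0)
    return SASMesh(vertices=v, triangles=f)


@pytest.fixture(scope="session")
def cap60() -> SASMesh:
    """Analytic spherical cap, R = 300 nm, half-angle 60 degrees."""
    v, f = cap_surface_mesh(300.0, math.radians(60), n_rings=60)
    return SASMesh(vertices=v, triangles=f)


@pytest.fixture(scope="session")
def hemisphere() -> SASMesh:
    """Analytic hemisphere, R = 100 nm."""
    v, f = cap_surface_mesh(100.0, math.pi / 2, n_rings=80)
    return SASMesh(vertices=v, triangles=f)


def make_cap_spec(area_nm2: float, curvature: float, orientation,
                  **kwargs) -> synthgen.PhantomSpec:
    """Phantom spec with the cap solved from target area and curvature."""
    theta = math.acos(1 - 2 * curvature)
    radius = math.sqrt(area_nm2 / (4 * math.pi * curvature))
    return synthgen.PhantomSpec(sphere_radius_nm=radius, cap_angle_rad=theta,
                                orientation=orientation, **kwargs)


@pytest.fixture(scope="session")
def pipelined_cap():
    """One typical cap phantom run through the full noise-free pipeline."""
    spec = make_cap_spec(65_000.0, 0.10, (0.25, -0.4, 0.88))
    res = experiments.measure_phantom(spec, seed=11, noise_sd=0.0)
    assert res.record is not None, res.error
    return res
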