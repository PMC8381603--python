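"""Shared fixtures: small meshes, fiber fields and material parameters.

Heavier session-scoped fixtures (full simulations) live in
tests/test_acceptance.py next to the checks that consume them.
"""

import numpy as np
import pytest

from cardiogrowth.constitutive import MaterialParams
from cardiogrowth.fibers import FiberField, assign_fibers
from cardiogrowth.geometry import LVShapeSpec, box_mesh, generate_idealized_lv


@pytest.fixture(scope="session")
def lv_spec():
    return LVShapeSpec()


@pytest.fixture(scope="session")
def lv_mesh(lv_spec):
    return generate_idealized_lv(lv_spec)


@pytest.fixture(scope="session")
def lv_fibers(lv_mesh):
    return assign_fibers(lv_mesh)


@pytest.fixture(scope="session")
def tiny_lv_mesh():
    spec = LVShapeSpec(n_circumferential=8, n_transmural=2, n_longitudinal=3)
    return generate_idealized_lv(spec)


@pytest.fixture(scope="session")
def hemisphere_spec():
    """Equal radii + equal wall thickness + truncation at the equator: a
    concentric hemispherical shell (r 20..26 mm)."""
    return LVShapeSpec(
        endo_long_radius=20.0,
        endo_short_radius=20.0,
        wall_thickness_apex=6.0,
        wall_thickness_equator=6.0,
        truncation_fraction=0.5,
        n_circumferential=16,
        n_transmural=4,
        n_longitudinal=8,
    )


@pytest.fixture(scope="session")
def hemisphere_mesh(hemisphere_spec):
    return generate_idealized_lv(hemisphere_spec)


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture()
def uniform_fibers():
    """Homogeneous axis-aligned triad for a given element count."""

    def make(ne: int) -> FiberField:
        return FiberField(
            f=np.tile([1.0, 0.0, 0.0], (ne, 1)),
            s=np.tile([0.0, 1.0, 0.0], (ne, 1)),
            n=np.tile([0.0, 0.0, 1.0], (ne, 1)),
            t_m=np.full(ne, 0.5),
        )

    return make


@pytest.fixture()
def free_block(uniform_fibers):
    """2x2x2-element cube with no constrained nodes (rigid modes damped)."""
    mesh = box_mesh(2, 2, 2, (2.0, 2.0, 2.0))
    mesh.node_sets["base"] = np.array([], dtype=np.int64)
    return mesh, uniform_fibers(mesh.n_elements)


def random_states(n, rng, max_dev=0.2, det_range=(0.8, 1.3)):
    """Random deformation gradients with controlled determinant and a unit
    orthonormal (f, s) pair; shared by constitutive and solver oracles."""
    F = np.eye(3) + max_dev * rng.standard_normal((n, 3, 3))
    d = np.linalg.det(F)
    F[d < 0] *= -1
    d = np.abs(d)
    scale = (rng.uniform(*det_range, n) / d) ** (1.0 / 3.0)
    F *= scale[:, None, None]
    f = rng.standard_normal((n, 3))
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    tmp = rng.standard_normal((n, 3))
    s = tmp - (tmp * f).sum(1, keepdims=True) * f
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    return F, f, s
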