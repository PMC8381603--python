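"""Rule-based myocardial fiber architecture (Laplace--Dirichlet method).

Two harmonic interpolation problems are solved on the mechanics mesh with
trilinear hex elements: a transmural field (0 on the endocardium, 1 on the
epicardium) and an apicobasal field (0 at the apex, 1 on the basal plane),
both with natural zero-flux conditions elsewhere.  Their gradients define
local transmural and longitudinal directions from which a per-element
orthonormal triad (f fiber, s sheetlet, n sheet-normal) is assembled, with
the helix angle interpolated linearly across the wall.

Only the transmural + apicobasal construction of the full rule-based
algorithm is implemented; ventricular/septal interpolation rules do not
apply to a single-chamber idealized wall.  The sheet angle is fixed at 0
(s transmural).  Sign convention: +60 deg at the endocardium, -60 deg at
the epicardium (right-handed helix at the endo side); configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import HexMesh, shape_gradients

__all__ = ["FiberField", "solve_laplace", "solve_transmural_laplace", "solve_apicobasal_laplace", "assign_fibers"]


@dataclass
class FiberField:
    """Per-element orthonormal microstructure triad and transmural coordinate."""

    f: np.ndarray  # (ne, 3) fiber
    s: np.ndarray  # (ne, 3) sheetlet
    n: np.ndarray  # (ne, 3) sheet-normal
    t_m: np.ndarray  # (ne,) transmural coordinate, 0 endo .. 1 epi
    helix_angle_endo: float = 60.0
    helix_angle_epi: float = -60.0

    def check(self, tol: float = 1e-9) -> None:
        for v in (self.f, self.s, self.n):
            if np.abs(np.linalg.norm(v, axis=1) - 1.0).max() > tol:
                raise ValueError("triad vectors are not unit length")
        if max(
            np.abs((self.f * self.s).sum(1)).max(),
            np.abs((self.f * self.n).sum(1)).max(),
            np.abs((self.s * self.n).sum(1)).max(),
        ) > tol:
            raise ValueError("triad is not orthogonal")
        if np.abs(np.cross(self.f, self.s) - self.n).max() > 1e-8:
            raise ValueError("triad is not right-handed (f x s != n)")


def _stiffness(mesh: HexMesh) -> sp.csr_matrix:
    dNdX, detJ = shape_gradients(mesh.nodes, mesh.elements)
    Ke = np.einsum("egai,egbi,eg->eab", dNdX, dNdX, detJ)  # (ne, 8, 8)
    e = mesh.elements
    rows = np.repeat(e, 8, axis=1).ravel()
    cols = np.tile(e, (1, 8)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes,) * 2)
    return K.tocsr()


def solve_laplace(mesh: HexMesh, dirichlet: dict) -> np.ndarray:
    """Solve the discrete Laplace equation with nodal Dirichlet data.

    ``dirichlet`` maps node-index arrays to scalar boundary values; all
    other boundaries receive the natural zero-flux condition.
    """
    K = _stiffness(mesh)
    n = mesh.n_nodes
    ncomp, _ = sp.csgraph.connected_components(K, directed=False)
    if ncomp > 1:
        raise RuntimeError(f"singular Laplace system: mesh has {ncomp} disconnected components")
    fixed = np.zeros(n, dtype=bool)
    vals = np.zeros(n)
    for ids, v in dirichlet.items():
        ids = np.asarray(ids)
        fixed[ids] = True
        vals[ids] = v
    free = ~fixed
    rhs = -K[free][:, fixed] @ vals[fixed]
    Kff = K[free][:, free].tocsc()
    try:
        sol = spla.spsolve(Kff, rhs)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError("singular Laplace system: is the mesh connected?") from exc
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("singular Laplace system: is the mesh connected?")
    out = vals.copy()
    out[free] = sol
    return out


def solve_transmural_laplace(mesh: HexMesh) -> np.ndarray:
    """Nodal transmural coordinate: 0 on the endocardium, 1 on the epicardium."""
    ns = mesh.node_sets
    if "endo_surface" not in ns or "epi_surface" not in ns:
        raise ValueError("mesh lacks endo/epi surface node sets")
    t = solve_laplace(mesh, {tuple(ns["endo_surface"]): 0.0, tuple(ns["epi_surface"]): 1.0})
    return np.clip(t, 0.0, 1.0)


def solve_apicobasal_laplace(mesh: HexMesh) -> np.ndarray:
    """Nodal apicobasal coordinate: 0 at the apex, 1 on the basal plane."""
    ns = mesh.node_sets
    return np.clip(solve_laplace(mesh, {tuple(ns["apex"]): 0.0, tuple(ns["base"]): 1.0}), 0.0, 1.0)


def _element_gradient(mesh: HexMesh, field: np.ndarray) -> np.ndarray:
    dNdX, detJ = shape_gradients(mesh.nodes, mesh.elements)
    g = np.einsum("egai,ea->egi", dNdX, field[mesh.elements])
    return g.mean(axis=1)


def assign_fibers(
    mesh: HexMesh,
    t_m: np.ndarray = None,
    angles: tuple = (60.0, -60.0),
) -> FiberField:
    """Build the per-element fiber/sheetlet/sheet-normal triad.

    The helix angle rotates linearly from ``angles[0]`` at the endocardium
    to ``angles[1]`` at the epicardium (default +60 to -60 degrees) in the
    plane spanned by the local circumferential and longitudinal directions.
    """
    if t_m is None:
        t_m = solve_transmural_laplace(mesh)
    ab = solve_apicobasal_laplace(mesh)

    grad_t = _element_gradient(mesh, t_m)
    norm_t = np.linalg.norm(grad_t, axis=1)
    if np.any(norm_t < 1e-12):
        bad = int(np.argmin(norm_t))
        raise ValueError(f"zero transmural gradient in element {bad}")
    e_t = grad_t / norm_t[:, None]

    grad_ab = _element_gradient(mesh, ab)
    e_l = grad_ab - (grad_ab * e_t).sum(1, keepdims=True) * e_t
    norm_l = np.linalg.norm(e_l, axis=1)
    if np.any(norm_l < 1e-12):
        bad = int(np.argmin(norm_l))
        raise ValueError(f"degenerate longitudinal direction in element {bad}")
    e_l /= norm_l[:, None]
    e_c = np.cross(e_l, e_t)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)

    tm_e = t_m[mesh.elements].mean(axis=1)
    theta = np.deg2rad(angles[0] + (angles[1] - angles[0]) * tm_e)
    f = np.cos(theta)[:, None] * e_c + np.sin(theta)[:, None] * e_l
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    s = e_t - (e_t * f).sum(1, keepdims=True) * f
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    n = np.cross(f, s)
    field = FiberField(f=f, s=s, n=n, t_m=tm_e, helix_angle_endo=angles[0], helix_angle_epi=angles[1])
    field.check()
    return field
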