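"""Idealized left-ventricular geometry and hexahedral mesh generation.

The LV wall is modeled as a truncated prolate spheroid: confocal-like endo-
and epicardial quadrics with a prescribed wall-thickness interpolation from
apex to base, cut by a basal plane of constant z.  Coordinate convention:
the LV long axis is +z, the base sits at high z and the apex at low z; all
lengths are millimetres.

The apex is closed with a structured "butterfly" (O-grid) block layout --
a square patch mapped onto the polar cap -- so that no hexahedron is
degenerate and the explicit solver's stable-increment estimate stays sound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LVShapeSpec",
    "HexMesh",
    "PericardialShell",
    "generate_idealized_lv",
    "build_pericardium",
    "box_mesh",
    "hex_gauss_points",
    "shape_gradients",
    "element_jacobians",
    "element_volumes",
    "enclosed_volume",
    "surface_area",
]

# 2x2x2 Gauss quadrature on the bi-unit hex (all weights 1)
_G = 1.0 / np.sqrt(3.0)


def hex_gauss_points() -> np.ndarray:
    """Return the 8 Gauss points of the 2x2x2 rule on [-1,1]^3, shape (8, 3)."""
    pts = []
    for k in (-_G, _G):
        for j in (-_G, _G):
            for i in (-_G, _G):
                pts.append((i, j, k))
    return np.array(pts)


def _shape_fn_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/dxi for the 8 trilinear shape functions at points xi (m,3) -> (m,8,3)."""
    # vertex signs in standard C3D8 order
    s = np.array(
        [
            [-1, -1, -1],
            [1, -1, -1],
            [1, 1, -1],
            [-1, 1, -1],
            [-1, -1, 1],
            [1, -1, 1],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=float,
    )
    xi = np.atleast_2d(xi)
    m = xi.shape[0]
    out = np.empty((m, 8, 3))
    for a in range(8):
        sa = s[a]
        f = 0.125 * (1 + sa * xi)  # (m,3) factors
        out[:, a, 0] = sa[0] * 0.125 * (1 + sa[1] * xi[:, 1]) * (1 + sa[2] * xi[:, 2])
        out[:, a, 1] = sa[1] * 0.125 * (1 + sa[0] * xi[:, 0]) * (1 + sa[2] * xi[:, 2])
        out[:, a, 2] = sa[2] * 0.125 * (1 + sa[0] * xi[:, 0]) * (1 + sa[1] * xi[:, 1])
        del f
    return out


_DN_DXI = _shape_fn_gradients(hex_gauss_points())  # (8 gp, 8 nodes, 3)


def shape_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Reference shape-function gradients and Jacobian determinants.

    Returns ``(dNdX, detJ)`` with shapes (ne, 8gp, 8nodes, 3) and (ne, 8gp).
    """
    X = nodes[elements]  # (ne, 8, 3)
    # J_ij = sum_a dN_a/dxi_j X_a_i  -> (ne, gp, 3, 3)
    J = np.einsum("gaj,eai->egij", _DN_DXI, X)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dNdX = np.einsum("gaj,egji->egai", _DN_DXI, Jinv)
    return dNdX, detJ


def element_jacobians(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Jacobian determinant at every 2x2x2 Gauss point, shape (ne, 8)."""
    X = nodes[elements]
    J = np.einsum("gaj,eai->egij", _DN_DXI, X)
    return np.linalg.det(J)


def element_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Per-element volume by 2x2x2 Gauss integration of det J."""
    return element_jacobians(nodes, elements).sum(axis=1)


def _quad_quadrature(nodes: np.ndarray, quads: np.ndarray):
    """Position, un-normalized normal (cross-product) at 2x2 Gauss points.

    Returns ``x`` (nf, 4gp, 3) and ``nda`` (nf, 4gp, 3); the normal's length
    is the area element (weights are 1).
    """
    X = nodes[quads]  # (nf, 4, 3)
    gp = np.array([(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)])
    s = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    N = 0.25 * (1 + gp[:, None, 0] * s[None, :, 0]) * (1 + gp[:, None, 1] * s[None, :, 1])
    dN = np.empty((4, 4, 2))
    dN[:, :, 0] = 0.25 * s[None, :, 0] * (1 + gp[:, None, 1] * s[None, :, 1])
    dN[:, :, 1] = 0.25 * s[None, :, 1] * (1 + gp[:, None, 0] * s[None, :, 0])
    x = np.einsum("ga,eai->egi", N, X)
    t1 = np.einsum("ga,eai->egi", dN[:, :, 0], X)
    t2 = np.einsum("ga,eai->egi", dN[:, :, 1], X)
    nda = np.cross(t1, t2)
    return x, nda


def enclosed_volume(nodes: np.ndarray, quads: np.ndarray) -> float:
    """Signed volume enclosed by an outward-oriented closed quad surface.

    Divergence-theorem identity V = (1/3) surface integral of x . n dA.
    """
    x, nda = _quad_quadrature(nodes, quads)
    return float(np.einsum("egi,egi->", x, nda) / 3.0)


def surface_area(nodes: np.ndarray, quads: np.ndarray) -> float:
    """Total area of a quad surface (2x2 Gauss)."""
    _, nda = _quad_quadrature(nodes, quads)
    return float(np.linalg.norm(nda, axis=2).sum())


@dataclass
class LVShapeSpec:
    """Parameters of the idealized truncated-prolate-spheroid LV wall.

    ``truncation_fraction`` is the fraction of the long axis retained below
    the basal cutting plane, so the basal plane sits at
    ``z = endo_long_radius * (2 * truncation_fraction - 1)``.
    """

    endo_long_radius: float = 16.0
    endo_short_radius: float = 10.0
    wall_thickness_apex: float = 3.5
    wall_thickness_equator: float = 4.0
    truncation_fraction: float = 0.8
    n_circumferential: int = 16
    n_transmural: int = 3
    n_longitudinal: int = 6

    def validate(self) -> None:
        if min(self.endo_long_radius, self.endo_short_radius) <= 0:
            raise ValueError("radii must be positive")
        if min(self.wall_thickness_apex, self.wall_thickness_equator) <= 0:
            raise ValueError("wall thickness must be positive")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation_fraction must lie in (0, 1)")
        if self.n_transmural < 2:
            raise ValueError("need at least 2 transmural element layers")
        if self.n_circumferential < 8 or self.n_circumferential % 8:
            raise ValueError("n_circumferential must be a multiple of 8 (butterfly apex)")
        if self.n_longitudinal < 2:
            raise ValueError("n_longitudinal must be >= 2")

    @classmethod
    def from_edge_length(
        cls,
        edge_length: float,
        *,
        endo_long_radius: float = 16.0,
        endo_short_radius: float = 10.0,
        wall_thickness_apex: float = 3.5,
        wall_thickness_equator: float = 4.0,
        truncation_fraction: float = 0.8,
    ) -> "LVShapeSpec":
        """Derive element counts from a target element edge length (mm).

        Rejects specifications whose wall is thinner than two element edges,
        which could not honor the minimum of two transmural layers.
        """
        wt = min(wall_thickness_apex, wall_thickness_equator)
        if wt < 2.0 * edge_length:
            raise ValueError(
                f"wall thickness {wt} mm < 2 x element edge {edge_length} mm: "
                "cannot honor >= 2 transmural element layers"
            )
        n_t = max(2, int(round(wall_thickness_equator / edge_length)))
        r_mid = endo_short_radius + 0.5 * wall_thickness_equator
        n_c = max(8, int(round(2 * np.pi * r_mid / edge_length / 8.0)) * 8)
        zb = endo_long_radius * (2 * truncation_fraction - 1)
        arc = endo_long_radius * np.arccos(np.clip(-zb / endo_long_radius, -1, 1))
        n_l = max(2, int(round(arc / edge_length)))
        return cls(
            endo_long_radius,
            endo_short_radius,
            wall_thickness_apex,
            wall_thickness_equator,
            truncation_fraction,
            n_c,
            n_t,
            n_l,
        )


@dataclass
class HexMesh:
    """Hexahedral LV mesh with labelled boundary surfaces.

    ``surface_sets`` maps surface names (``endo``, ``epi``, ``base``) to
    (nf, 4) arrays of node indices forming quad facets oriented with outward
    normals (pointing away from the solid).  ``node_sets`` holds named node
    index arrays (``base``, ``apex``, ``endo_surface``, ``epi_surface``).
    """

    nodes: np.ndarray
    elements: np.ndarray
    surface_sets: dict = field(default_factory=dict)
    node_sets: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def jacobians(self) -> np.ndarray:
        return element_jacobians(self.nodes, self.elements)

    def volumes(self) -> np.ndarray:
        return element_volumes(self.nodes, self.elements)

    def check(self) -> None:
        """Raise if any element Jacobian is non-positive or a set is missing."""
        detJ = self.jacobians()
        if not np.all(detJ > 0):
            bad = np.where((detJ <= 0).any(axis=1))[0]
            raise ValueError(f"non-positive Jacobian in elements {bad[:10].tolist()}")
        for name in ("endo", "epi"):
            if name not in self.surface_sets:
                raise ValueError(f"missing surface set {name!r}")


@dataclass
class PericardialShell:
    """Quad shell conforming to the epicardial surface.

    The pericardium is treated as a linear elastic membrane (Young's modulus
    in MPa, default 10 MPa) whose basal ring is constrained longitudinally.
    """

    nodes: np.ndarray
    elements: np.ndarray  # (nf, 4) quad connectivity
    base_ring_nodes: np.ndarray
    thickness: float = 0.25  # mm
    youngs_modulus: float = 10.0  # MPa
    poisson_ratio: float = 0.3


def _squircle(xi: np.ndarray, eta: np.ndarray):
    """Map the square [-1,1]^2 onto the unit disc (elliptical grid mapping)."""
    x = xi * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * eta**2))
    y = eta * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * xi**2))
    return x, y


def _fix_element_orientation(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Flip hexes with negative volume (swap bottom/top quad winding)."""
    detJ = element_jacobians(nodes, elements)
    flip = detJ.sum(axis=1) < 0
    if flip.any():
        e = elements.copy()
        e[flip] = e[flip][:, [0, 3, 2, 1, 4, 7, 6, 5]]
        return e
    return elements


def _orient_quads(nodes: np.ndarray, quads: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """Reorder each quad so its normal aligns with the given outward direction."""
    x, nda = _quad_quadrature(nodes, quads)
    n = nda.mean(axis=1)
    flip = np.einsum("fi,fi->f", n, outward) < 0
    q = quads.copy()
    q[flip] = q[flip][:, ::-1]
    return q


def generate_idealized_lv(spec: LVShapeSpec) -> HexMesh:
    """Build a structured hex mesh of a truncated prolate-spheroid LV wall.

    The transmural direction carries exactly ``spec.n_transmural`` element
    layers; the polar cap uses a butterfly (square-patch) layout so every
    hexahedron has a strictly positive Jacobian.
    """
    spec.validate()
    a_en, c_en = spec.endo_short_radius, spec.endo_long_radius
    a_ep = a_en + spec.wall_thickness_equator
    c_ep = c_en + spec.wall_thickness_apex
    z_b = c_en * (2.0 * spec.truncation_fraction - 1.0)
    if z_b >= c_en:
        raise ValueError("truncation does not produce an open basal plane")

    m = spec.n_circumferential // 4  # square-patch side divisions (even)
    n_long, n_t, n_c = spec.n_longitudinal, spec.n_transmural, spec.n_circumferential
    q_cap = 0.5 * m / (0.5 * m + n_long)

    theta_b = {
        "endo": np.arccos(np.clip(-z_b / c_en, -1.0, 1.0)),
        "epi": np.arccos(np.clip(-z_b / c_ep, -1.0, 1.0)),
    }
    axes = {"endo": (a_en, c_en), "epi": (a_ep, c_ep)}

    # --- parametric samples: cap grid then band rings --------------------
    ii, jj = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
    xi = -1.0 + 2.0 * ii.ravel() / m
    eta = -1.0 + 2.0 * jj.ravel() / m
    cx, cy = _squircle(xi, eta)
    rho_cap = np.hypot(cx, cy)  # in [0, 1]
    phi_cap = np.arctan2(cy, cx)

    # boundary traversal (counter-clockwise) -> ring azimuths
    bidx = []
    for j in range(m):  # right side, phi -45..45
        bidx.append((m, j))
    for i in range(m, 0, -1):  # top
        bidx.append((i, m))
    for j in range(m, 0, -1):  # left
        bidx.append((0, j))
    for i in range(0, m):  # bottom
        bidx.append((i, 0))
    assert len(bidx) == n_c
    cap_flat = {(i, j): i * (m + 1) + j for i in range(m + 1) for j in range(m + 1)}
    bflat = np.array([cap_flat[ij] for ij in bidx])
    phi_ring = phi_cap[bflat]

    n_cap = (m + 1) ** 2
    npl = n_cap + n_long * n_c  # nodes per transmural layer

    def surf_points(which: str) -> np.ndarray:
        a, c = axes[which]
        th_cap = q_cap * theta_b[which]
        pts = np.empty((npl, 3))
        th = rho_cap * th_cap
        pts[:n_cap, 0] = a * np.sin(th) * np.cos(phi_cap)
        pts[:n_cap, 1] = a * np.sin(th) * np.sin(phi_cap)
        pts[:n_cap, 2] = -c * np.cos(th)
        for r in range(1, n_long + 1):
            th_r = th_cap + (theta_b[which] - th_cap) * r / n_long
            o = n_cap + (r - 1) * n_c
            pts[o : o + n_c, 0] = a * np.sin(th_r) * np.cos(phi_ring)
            pts[o : o + n_c, 1] = a * np.sin(th_r) * np.sin(phi_ring)
            pts[o : o + n_c, 2] = -c * np.cos(th_r)
        return pts

    P_en = surf_points("endo")
    P_ep = surf_points("epi")
    nodes = np.empty(((n_t + 1) * npl, 3))
    for w in range(n_t + 1):
        t = w / n_t
        nodes[w * npl : (w + 1) * npl] = (1 - t) * P_en + t * P_ep

    def cap_id(w, i, j):
        return w * npl + i * (m + 1) + j

    def ring_id(w, r, k):
        if r == 0:
            return w * npl + bflat[k % n_c]
        return w * npl + n_cap + (r - 1) * n_c + (k % n_c)

    # --- elements --------------------------------------------------------
    elems = []
    for w in range(n_t):
        for i in range(m):
            for j in range(m):
                b = [cap_id(w, i, j), cap_id(w, i + 1, j), cap_id(w, i + 1, j + 1), cap_id(w, i, j + 1)]
                t = [cap_id(w + 1, i, j), cap_id(w + 1, i + 1, j), cap_id(w + 1, i + 1, j + 1), cap_id(w + 1, i, j + 1)]
                elems.append(b + t)
        for r in range(n_long):
            for k in range(n_c):
                b = [ring_id(w, r, k), ring_id(w, r, k + 1), ring_id(w, r + 1, k + 1), ring_id(w, r + 1, k)]
                t = [ring_id(w + 1, r, k), ring_id(w + 1, r, k + 1), ring_id(w + 1, r + 1, k + 1), ring_id(w + 1, r + 1, k)]
                elems.append(b + t)
    elements = _fix_element_orientation(nodes, np.array(elems, dtype=np.int64))

    # --- surface facets --------------------------------------------------
    def layer_quads(w):
        qs = []
        param = []  # flat parametric index, for outward direction lookup
        for i in range(m):
            for j in range(m):
                qs.append([cap_id(w, i, j), cap_id(w, i + 1, j), cap_id(w, i + 1, j + 1), cap_id(w, i, j + 1)])
                param.append(cap_flat[(i, j)])
        for r in range(n_long):
            for k in range(n_c):
                qs.append([ring_id(w, r, k), ring_id(w, r, k + 1), ring_id(w, r + 1, k + 1), ring_id(w, r + 1, k)])
                param.append(bflat[k] if r == 0 else n_cap + (r - 1) * n_c + k)
        return np.array(qs, dtype=np.int64), np.array(param)

    trans_dir = P_ep - P_en  # endo -> epi outward direction per parametric node
    endo_q, pidx = layer_quads(0)
    endo_q = _orient_quads(nodes, endo_q, -trans_dir[pidx])
    epi_q, pidx = layer_quads(n_t)
    epi_q = _orient_quads(nodes, epi_q, trans_dir[pidx])
    base_q = []
    for w in range(n_t):
        for k in range(n_c):
            base_q.append([ring_id(w, n_long, k), ring_id(w, n_long, k + 1), ring_id(w + 1, n_long, k + 1), ring_id(w + 1, n_long, k)])
    base_q = _orient_quads(nodes, np.array(base_q, dtype=np.int64), np.tile([0.0, 0.0, 1.0], (n_c * n_t, 1)))

    base_nodes = np.array([ring_id(w, n_long, k) for w in range(n_t + 1) for k in range(n_c)], dtype=np.int64)
    apex_nodes = np.array([cap_id(w, m // 2, m // 2) for w in range(n_t + 1)], dtype=np.int64)
    endo_nodes = np.arange(npl, dtype=np.int64)
    epi_nodes = np.arange(n_t * npl, (n_t + 1) * npl, dtype=np.int64)

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        surface_sets={"endo": endo_q, "epi": epi_q, "base": base_q},
        node_sets={
            "base": base_nodes,
            "apex": apex_nodes,
            "endo_surface": endo_nodes,
            "epi_surface": epi_nodes,
        },
        metadata={
            "layout": "truncated-prolate-spheroid butterfly apex",
            "basal_plane_z": z_b,
            "spec": spec.__dict__.copy(),
        },
    )
    mesh.check()
    return mesh


def build_pericardium(mesh: HexMesh, thickness: float = 0.25, E: float = 10.0, poisson_ratio: float = 0.3, clearance: float = 0.0) -> PericardialShell:
    """Construct a quad pericardial shell conforming to the epicardium.

    The shell reuses the epicardial surface facets node-for-node (optionally
    offset outward along the nodal normal by ``clearance`` mm).  Its basal
    ring is every shell node lying in the basal plane.
    """
    if "epi" not in mesh.surface_sets:
        raise ValueError("mesh has no epicardial surface set")
    epi_q = mesh.surface_sets["epi"]
    used = np.unique(epi_q)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(used.size)
    shell_nodes = mesh.nodes[used].copy()
    shell_elems = remap[epi_q]
    if clearance:
        # average outward facet normal per node
        _, nda = _quad_quadrature(mesh.nodes, epi_q)
        fn = nda.mean(axis=1)
        fn /= np.linalg.norm(fn, axis=1, keepdims=True)
        nn = np.zeros((used.size, 3))
        for f, quad in enumerate(shell_elems):
            nn[quad] += fn[f]
        nn /= np.maximum(np.linalg.norm(nn, axis=1, keepdims=True), 1e-30)
        shell_nodes += clearance * nn
    z_b = mesh.metadata.get("basal_plane_z", mesh.nodes[:, 2].max())
    ring = np.where(np.abs(shell_nodes[:, 2] - z_b) < 1e-8 * max(1.0, abs(z_b)) + 1e-9)[0]
    if ring.size == 0:  # tolerance fallback: topmost nodes
        zmax = shell_nodes[:, 2].max()
        ring = np.where(shell_nodes[:, 2] > zmax - 1e-6)[0]
    return PericardialShell(
        nodes=shell_nodes,
        elements=shell_elems,
        base_ring_nodes=ring,
        thickness=thickness,
        youngs_modulus=E,
        poisson_ratio=poisson_ratio,
    )


def box_mesh(nx: int, ny: int, nz: int, lengths=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> HexMesh:
    """Structured box mesh (testing and benchmark utility).

    Surface sets: ``endo`` is the x=0 face, ``epi`` the x=Lx face and
    ``base`` the z=Lz face, mimicking the labelling of the LV wall so the
    same Laplace/fiber machinery runs on a slab.
    """
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    elements = _fix_element_orientation(nodes, np.array(elems, dtype=np.int64))

    def face_quads(fixed, at_end):
        qs = []
        if fixed == "x":
            i = nx if at_end else 0
            for j in range(ny):
                for k in range(nz):
                    qs.append([nid(i, j, k), nid(i, j + 1, k), nid(i, j + 1, k + 1), nid(i, j, k + 1)])
            out = np.array([1.0, 0, 0]) if at_end else np.array([-1.0, 0, 0])
        else:
            k = nz if at_end else 0
            for i in range(nx):
                for j in range(ny):
                    qs.append([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k)])
            out = np.array([0, 0, 1.0]) if at_end else np.array([0, 0, -1.0])
        qs = np.array(qs, dtype=np.int64)
        return _orient_quads(nodes, qs, np.tile(out, (len(qs), 1)))

    endo_q = face_quads("x", False)
    epi_q = face_quads("x", True)
    base_q = face_quads("z", True)
    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        surface_sets={"endo": endo_q, "epi": epi_q, "base": base_q},
        node_sets={
            "endo_surface": np.unique(endo_q),
            "epi_surface": np.unique(epi_q),
            "base": np.unique(base_q),
            "apex": np.unique(face_quads("z", False)),
        },
        metadata={"layout": "box"},
    )
    mesh.check()
    return mesh
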