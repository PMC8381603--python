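"""Per-slice endo/epi contour stacks and contour-based meshing.

A contour stack emulates the output of short-axis CMR segmentation: an
ordered list of slices (apex to base), each carrying a closed endocardial
and epicardial contour in the slice plane.  Through-slice discontinuities
from per-slice segmentation are removed by smoothing each contour control
point along the slice direction with a cubic smoothing spline; the smoothed
stack can then be lofted into a structured hexahedral wall mesh.

A stack covers only the imaged z-range, so contour-based meshes are open
at both ends (tube topology; the ``base`` surface is the top annulus).
Closed-apex meshes come from the idealized-geometry generator.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline, make_smoothing_spline

from .geometry import HexMesh, LVShapeSpec, _fix_element_orientation, _orient_quads

__all__ = ["ContourSlice", "ContourStack", "contours_from_spec", "smooth_contour_stack", "mesh_from_contours"]


@dataclass
class ContourSlice:
    slice_z: float
    endo_points: np.ndarray  # (n, 2) mm
    epi_points: np.ndarray  # (n, 2) mm


@dataclass
class ContourStack:
    """Ordered short-axis contour slices, apex (low z) to base (high z)."""

    slices: list
    in_plane_spacing: float = 1.4
    slice_thickness: float = 2.5

    def validate(self) -> None:
        if len(self.slices) < 3:
            raise ValueError("need at least 3 slices")
        zs = [s.slice_z for s in self.slices]
        if not np.all(np.diff(zs) > 0):
            raise ValueError("slice_z must increase strictly from apex to base")
        for s in self.slices:
            re = np.linalg.norm(s.endo_points - s.endo_points.mean(0), axis=1)
            rp = np.linalg.norm(s.epi_points - s.epi_points.mean(0), axis=1)
            if rp.min() <= re.max() and rp.mean() <= re.mean():
                raise ValueError(f"epi contour does not enclose endo contour at z={s.slice_z}")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["slice_z", "contour_id", "x", "y"])
            for s in self.slices:
                for cid, pts in (("endo", s.endo_points), ("epi", s.epi_points)):
                    for x, y in pts:
                        w.writerow([s.slice_z, cid, x, y])

    @classmethod
    def from_csv(cls, path, in_plane_spacing: float = 1.4, slice_thickness: float = 2.5) -> "ContourStack":
        rows = {}
        with open(path) as fh:
            for rec in csv.DictReader(fh):
                key = float(rec["slice_z"])
                rows.setdefault(key, {"endo": [], "epi": []})[rec["contour_id"]].append(
                    (float(rec["x"]), float(rec["y"]))
                )
        slices = [
            ContourSlice(z, np.array(d["endo"]), np.array(d["epi"])) for z, d in sorted(rows.items())
        ]
        return cls(slices, in_plane_spacing, slice_thickness)

    def to_json(self, path) -> None:
        data = {
            "in_plane_spacing": self.in_plane_spacing,
            "slice_thickness": self.slice_thickness,
            "slices": [
                {"slice_z": s.slice_z, "endo": s.endo_points.tolist(), "epi": s.epi_points.tolist()}
                for s in self.slices
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "ContourStack":
        with open(path) as fh:
            d = json.load(fh)
        slices = [ContourSlice(s["slice_z"], np.array(s["endo"]), np.array(s["epi"])) for s in d["slices"]]
        return cls(slices, d["in_plane_spacing"], d["slice_thickness"])


def contours_from_spec(spec: LVShapeSpec, n_slices: int = 10, n_points: int = 48, z_lo_frac: float = 0.35) -> ContourStack:
    """Sample per-slice contours from the idealized LV quadric surfaces.

    Slices span from ``z_lo_frac`` of the way up the endocardial long axis
    (above the apex, as short-axis imaging does) to the basal plane.
    """
    a_en, c_en = spec.endo_short_radius, spec.endo_long_radius
    a_ep = a_en + spec.wall_thickness_equator
    c_ep = c_en + spec.wall_thickness_apex
    z_b = c_en * (2.0 * spec.truncation_fraction - 1.0)
    z0 = -c_en + z_lo_frac * (z_b + c_en)
    zs = np.linspace(z0, z_b, n_slices)
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    slices = []
    for z in zs:
        r_en = a_en * np.sqrt(max(0.0, 1.0 - (z / c_en) ** 2))
        r_ep = a_ep * np.sqrt(max(0.0, 1.0 - (z / c_ep) ** 2))
        endo = np.stack([r_en * np.cos(phi), r_en * np.sin(phi)], axis=1)
        epi = np.stack([r_ep * np.cos(phi), r_ep * np.sin(phi)], axis=1)
        slices.append(ContourSlice(float(z), endo, epi))
    stack = ContourStack(slices)
    stack.validate()
    return stack


def _self_intersects(pts: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon

        return not Polygon(pts).is_valid
    except Exception:  # pragma: no cover
        return False


def smooth_contour_stack(stack: ContourStack, smoothing: float = None) -> ContourStack:
    """Smooth corresponding control points along the slice direction.

    Each control point index traces a curve (x_i(z), y_i(z)) through the
    stack; both coordinates are fitted with cubic smoothing splines.
    ``smoothing`` is the curvature-penalty weight: ``None`` selects it by
    generalized cross-validation (noise-free smooth data passes through
    unchanged), 0 interpolates exactly, larger values smooth harder.
    Contours must have matching point counts across slices.  Degenerate
    (self-intersecting) smoothed contours raise a warning rather than
    passing silently.
    """
    stack.validate()
    if len(stack.slices) < 4:
        raise ValueError("need at least 4 slices for cubic smoothing along z")
    zs = np.array([s.slice_z for s in stack.slices])
    out_slices = [ContourSlice(s.slice_z, s.endo_points.copy(), s.epi_points.copy()) for s in stack.slices]
    for attr in ("endo_points", "epi_points"):
        P = np.stack([getattr(s, attr) for s in stack.slices])  # (nz, np, 2)
        for ipt in range(P.shape[1]):
            for ax in range(2):
                if smoothing == 0:
                    spl = UnivariateSpline(zs, P[:, ipt, ax], k=3, s=0)
                else:
                    spl = make_smoothing_spline(zs, P[:, ipt, ax], lam=smoothing)
                P[:, ipt, ax] = spl(zs)
        for iz, s in enumerate(out_slices):
            setattr(s, attr, P[iz])
    for s in out_slices:
        for name, pts in (("endo", s.endo_points), ("epi", s.epi_points)):
            if _self_intersects(pts):
                warnings.warn(
                    f"smoothed {name} contour at z={s.slice_z} self-intersects",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return ContourStack(out_slices, stack.in_plane_spacing, stack.slice_thickness)


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed 2D polyline to n points by arclength, starting at
    the direction of +x from the centroid."""
    c = pts.mean(0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    order = np.argsort(ang)
    p = pts[order]
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    tt = np.linspace(0, t[-1], n, endpoint=False)
    x = np.interp(tt, t, closed[:, 0])
    y = np.interp(tt, t, closed[:, 1])
    return np.stack([x, y], axis=1)


def mesh_from_contours(stack: ContourStack, n_transmural: int = 3, n_circumferential: int = 16) -> HexMesh:
    """Loft a contour stack into a structured hexahedral wall mesh.

    Slices become circumferential node rings; the wall is interpolated
    linearly from endo to epi across ``n_transmural`` element layers.  The
    resulting mesh is open at both ends (tube topology over the imaged
    z-range); the basal (top) annulus forms the ``base`` surface.
    """
    stack.validate()
    n_c, n_t = n_circumferential, n_transmural
    nz = len(stack.slices)
    endo_rings = []
    epi_rings = []
    for s in stack.slices:
        en2 = _resample_closed(np.asarray(s.endo_points, float), n_c)
        ep2 = _resample_closed(np.asarray(s.epi_points, float), n_c)
        re = np.linalg.norm(en2 - en2.mean(0), axis=1)
        rp = np.linalg.norm(ep2 - ep2.mean(0), axis=1)
        if rp.mean() <= re.mean():
            raise ValueError(f"epi contour radius below endo at z={s.slice_z}")
        endo_rings.append(np.column_stack([en2, np.full(n_c, s.slice_z)]))
        epi_rings.append(np.column_stack([ep2, np.full(n_c, s.slice_z)]))
    P_en = np.stack(endo_rings)  # (nz, nc, 3)
    P_ep = np.stack(epi_rings)

    npl = nz * n_c
    nodes = np.empty(((n_t + 1) * npl, 3))
    for w in range(n_t + 1):
        t = w / n_t
        nodes[w * npl : (w + 1) * npl] = ((1 - t) * P_en + t * P_ep).reshape(npl, 3)

    def nid(w, iz, k):
        return w * npl + iz * n_c + (k % n_c)

    elems = []
    for w in range(n_t):
        for iz in range(nz - 1):
            for k in range(n_c):
                b = [nid(w, iz, k), nid(w, iz, k + 1), nid(w, iz + 1, k + 1), nid(w, iz + 1, k)]
                t = [nid(w + 1, iz, k), nid(w + 1, iz, k + 1), nid(w + 1, iz + 1, k + 1), nid(w + 1, iz + 1, k)]
                elems.append(b + t)
    elements = _fix_element_orientation(nodes, np.array(elems, dtype=np.int64))

    out_dir = (P_ep - P_en).reshape(npl, 3)

    def layer_quads(w):
        qs, pidx = [], []
        for iz in range(nz - 1):
            for k in range(n_c):
                qs.append([nid(w, iz, k), nid(w, iz, k + 1), nid(w, iz + 1, k + 1), nid(w, iz + 1, k)])
                pidx.append(iz * n_c + k)
        return np.array(qs, dtype=np.int64), np.array(pidx)

    endo_q, pidx = layer_quads(0)
    endo_q = _orient_quads(nodes, endo_q, -out_dir[pidx])
    epi_q, pidx = layer_quads(n_t)
    epi_q = _orient_quads(nodes, epi_q, out_dir[pidx])
    base_q = []
    for w in range(n_t):
        for k in range(n_c):
            base_q.append([nid(w, nz - 1, k), nid(w, nz - 1, k + 1), nid(w + 1, nz - 1, k + 1), nid(w + 1, nz - 1, k)])
    base_q = _orient_quads(nodes, np.array(base_q, dtype=np.int64), np.tile([0.0, 0.0, 1.0], (n_c * n_t, 1)))

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        surface_sets={"endo": endo_q, "epi": epi_q, "base": base_q},
        node_sets={
            "endo_surface": np.arange(npl, dtype=np.int64),
            "epi_surface": np.arange(n_t * npl, (n_t + 1) * npl, dtype=np.int64),
            "base": np.array([nid(w, nz - 1, k) for w in range(n_t + 1) for k in range(n_c)], dtype=np.int64),
            "apex": np.array([nid(w, 0, k) for w in range(n_t + 1) for k in range(n_c)], dtype=np.int64),
        },
        metadata={"layout": "contour-lofted tube", "basal_plane_z": stack.slices[-1].slice_z},
    )
    mesh.check()
    return mesh
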