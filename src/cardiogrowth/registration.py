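"""Rigid point-cloud registration (iterative closest point).

Pre- and post-growth geometries live in scanner/model coordinates that may
differ by a rigid motion; before the DICE objective is evaluated the FE
node cloud is rigidly aligned to the target nodes.  The transform is
estimated by ICP: nearest-neighbor correspondences, Kabsch (SVD) update,
iterate to convergence.  No scaling, no shear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["RigidTransform", "rigid_register"]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    converged: bool = True
    rms: float = np.nan

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)

    def check(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > tol:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise ValueError("rotation is not proper (det != +1)")

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix().tolist(), "converged": bool(self.converged)}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        M = np.asarray(d["matrix"])
        return cls(M[:3, :3], M[:3, 3], bool(d.get("converged", True)))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _kabsch(src: np.ndarray, dst: np.ndarray):
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return R, t


def rigid_register(
    source: np.ndarray,
    target: np.ndarray,
    init: str = "pca",
    max_iter: int = 60,
    tol: float = 1e-8,
) -> RigidTransform:
    """Estimate the rigid transform mapping ``source`` onto ``target``.

    ICP with centroid + principal-axes initialization (``init='pca'``; use
    ``'identity'`` when the clouds are already nearly aligned, e.g. for
    near-axisymmetric LVs whose principal axes are degenerate).  Returns
    the best transform found; ``converged`` flags whether the mean-squared
    nearest-neighbor distance stopped improving within ``max_iter``.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape[0] < 4 or target.shape[0] < 4:
        raise ValueError("need at least 4 points in each cloud")

    tree = cKDTree(target)
    if init == "pca":
        # choose the sign combination with the lowest initial cost
        cs, cd = source.mean(0), target.mean(0)
        def axes(p):
            w, v = np.linalg.eigh(np.cov((p - p.mean(0)).T))
            v = v[:, ::-1]
            if np.linalg.det(v) < 0:
                v[:, 2] = -v[:, 2]
            return v
        Vs, Vd = axes(source), axes(target)
        R0, t0, best_cost = np.eye(3), cd - cs, np.inf
        for sx in (1, -1):
            for sy in (1, -1):
                S = np.diag([sx, sy, sx * sy])
                R = Vd @ S @ Vs.T
                t = cd - R @ cs
                d, _ = tree.query(source @ R.T + t)
                cost = float((d**2).mean())
                if cost < best_cost:
                    best_cost, R0, t0 = cost, R, t
        R, t = R0, t0
    else:
        R, t = np.eye(3), np.zeros(3)

    prev = np.inf
    converged = False
    rms = np.nan
    for _ in range(max_iter):
        moved = source @ R.T + t
        d, idx = tree.query(moved)
        cost = float((d**2).mean())
        if abs(prev - cost) <= tol * max(prev, 1e-30):
            converged = True
            rms = np.sqrt(cost)
            break
        prev = cost
        R, t = _kabsch(source, target[idx])
        rms = np.sqrt(cost)
    out = RigidTransform(R, t, converged=converged, rms=rms)
    out.check(tol=1e-9)
    return out
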