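"""Kinematic growth and Holzapfel--Ogden myocardium constitutive model.

The total deformation gradient is decomposed multiplicatively, F = Fe Fg.
Only the elastic part Fe = F Fg^-1 generates stress; the growth multiplier

    Fg = (1 + alpha_f) f (x) f + (1 + alpha_n) (s (x) s + n (x) n)

is a transversely isotropic stretch about the local fiber direction f:
``alpha_f`` models longitudinal (in-series) sarcomerogenesis and ``alpha_n``
transverse (in-parallel) sarcomerogenesis in the sheetlet/sheet-normal
plane.  The elastic response is the invariant-based anisotropic
Holzapfel--Ogden energy evaluated on the elastic right Cauchy--Green tensor
Ce = Fe^T Fe, with swine material parameters as defaults.

Conventions (documented deviations from the bare printed form of the
energy, selectable via flags):

* the exponential anisotropic terms are ``a_i/(2 b_i) {exp[b_i (I4i-1)^2] - 1}``
  so the anisotropic energy vanishes in the reference configuration;
* fiber/sheet terms act in tension only (Macaulay bracket on I4 - 1) by
  default, avoiding nonphysical compressive fiber stiffening;
* near-incompressibility is enforced with a volumetric penalty
  ``kappa/2 (ln Je)^2`` and an isochoric split of the I1 term.

Units: lengths mm, stresses kPa; 1 mmHg = 0.133322 kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_KPA",
    "GrowthParams",
    "MaterialParams",
    "DeformationState",
    "growth_tensor",
    "growth_tensor_inverse",
    "elastic_invariants",
    "strain_energy",
    "reference_energy",
    "pk2_stress",
]

MMHG_TO_KPA = 0.133322


@dataclass
class GrowthParams:
    """Longitudinal (fiber) and transverse (cross-fiber) growth coefficients.

    Both lie in [0, 1]: a value of 1 doubles the size in that direction,
    which bounds the inverse search space.
    """

    alpha_f: float = 0.0
    alpha_n: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.alpha_f <= 1.0 and 0.0 <= self.alpha_n <= 1.0):
            raise ValueError("growth coefficients must lie in [0, 1]")

    def scaled(self, fraction: float) -> "GrowthParams":
        return GrowthParams(self.alpha_f * fraction, self.alpha_n * fraction)

    def as_tuple(self):
        return (self.alpha_f, self.alpha_n)


@dataclass
class MaterialParams:
    """Holzapfel--Ogden parameters (kPa / dimensionless), swine defaults.

    ``bulk_modulus`` is the near-incompressibility penalty and ``density``
    a nominal mass density; the explicit solver rescales the density (mass
    scaling), so only its spatial uniformity matters.
    """

    a: float = 1.05
    b: float = 7.542
    a_f: float = 3.465
    b_f: float = 14.472
    a_s: float = 0.481
    b_s: float = 12.548
    a_fs: float = 0.283
    b_fs: float = 3.088
    bulk_modulus: float = 1000.0
    density: float = 1.0e-6
    tension_only: bool = True

    def validate(self) -> None:
        if min(self.a, self.a_f, self.a_s, self.a_fs) < 0:
            raise ValueError("'a' parameters must be non-negative")
        if min(self.b, self.b_f, self.b_s, self.b_fs) <= 0:
            raise ValueError("'b' exponents must be positive")
        if self.bulk_modulus < 100.0 * self.a:
            raise ValueError("bulk modulus must dominate the isotropic stiffness")

    def isotropic(self) -> "MaterialParams":
        """Copy with the anisotropic terms switched off (testing aid)."""
        out = MaterialParams(**self.__dict__)
        out.a_f = out.a_s = out.a_fs = 0.0
        return out


def growth_tensor(params: GrowthParams, f: np.ndarray, s: np.ndarray = None, n: np.ndarray = None) -> np.ndarray:
    """Transversely isotropic growth tensor for a unit fiber direction.

    Since s and n span the plane orthogonal to f, the tensor reduces to
    ``(1+alpha_n) I + (alpha_f - alpha_n) f (x) f``; s and n are accepted for
    interface symmetry but not required.  Batched over leading axes of f.
    """
    f = np.asarray(f, dtype=float)
    eye = np.broadcast_to(np.eye(3), f.shape[:-1] + (3, 3))
    ff = f[..., :, None] * f[..., None, :]
    return (1.0 + params.alpha_n) * eye + (params.alpha_f - params.alpha_n) * ff


def growth_tensor_inverse(params: GrowthParams, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    eye = np.broadcast_to(np.eye(3), f.shape[:-1] + (3, 3))
    ff = f[..., :, None] * f[..., None, :]
    return eye / (1.0 + params.alpha_n) + (1.0 / (1.0 + params.alpha_f) - 1.0 / (1.0 + params.alpha_n)) * ff


def elastic_invariants(Ce: np.ndarray, f: np.ndarray, s: np.ndarray):
    """I1e, I4fe, I4se, I8fse of the elastic right Cauchy--Green tensor."""
    I1 = np.trace(Ce, axis1=-2, axis2=-1)
    Cf = np.einsum("...ij,...j->...i", Ce, f)
    Cs = np.einsum("...ij,...j->...i", Ce, s)
    I4f = np.einsum("...i,...i->...", f, Cf)
    I4s = np.einsum("...i,...i->...", s, Cs)
    I8 = np.einsum("...i,...i->...", f, Cs)
    return I1, I4f, I4s, I8


@dataclass
class DeformationState:
    """Deformation at a material point: total, growth and elastic parts."""

    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray
    Ce: np.ndarray
    f: np.ndarray
    s: np.ndarray
    I1e: np.ndarray = field(default=None)
    I4fe: np.ndarray = field(default=None)
    I4se: np.ndarray = field(default=None)
    I8fse: np.ndarray = field(default=None)

    @classmethod
    def make(cls, F, growth: GrowthParams, f, s) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        Fg = growth_tensor(growth, f)
        Fe = F @ growth_tensor_inverse(growth, f)
        Ce = np.swapaxes(Fe, -1, -2) @ Fe
        I1, I4f, I4s, I8 = elastic_invariants(Ce, f, s)
        return cls(F, Fg, Fe, Ce, np.asarray(f, float), np.asarray(s, float), I1, I4f, I4s, I8)


def strain_energy(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Energy density per unit grown (intermediate-configuration) volume, kPa.

    Isochoric I1 term, tension-only anisotropic terms (if configured) and
    the volumetric penalty.  At Fe = I the anisotropic and volumetric parts
    vanish and the isotropic part equals the constant a/(2b).
    """
    Je = np.linalg.det(state.Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be positive")
    I1iso = Je ** (-2.0 / 3.0) * state.I1e
    psi = mat.a / (2.0 * mat.b) * np.exp(mat.b * (I1iso - 3.0))
    for ai, bi, I4 in ((mat.a_f, mat.b_f, state.I4fe), (mat.a_s, mat.b_s, state.I4se)):
        e = I4 - 1.0
        if mat.tension_only:
            e = np.maximum(e, 0.0)
        psi = psi + ai / (2.0 * bi) * (np.exp(bi * e**2) - 1.0)
    psi = psi + mat.a_fs / (2.0 * mat.b_fs) * (np.exp(mat.b_fs * state.I8fse**2) - 1.0)
    psi = psi + 0.5 * mat.bulk_modulus * np.log(Je) ** 2
    return psi


def reference_energy(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Energy density per unit reference (pre-growth) volume: det(Fg) * psi."""
    return np.linalg.det(state.Fg) * strain_energy(state, mat)


def _pk2_elastic(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Second Piola--Kirchhoff stress w.r.t. the grown configuration, 2 dpsi/dCe."""
    Ce = state.Ce
    Je2 = np.linalg.det(Ce)
    Je = np.sqrt(Je2)
    Cinv = np.linalg.inv(Ce)
    eye = np.broadcast_to(np.eye(3), Ce.shape)
    I1iso = Je ** (-2.0 / 3.0) * state.I1e

    coef = mat.a * np.exp(mat.b * (I1iso - 3.0)) * Je ** (-2.0 / 3.0)
    S = coef[..., None, None] * (eye - (state.I1e / 3.0)[..., None, None] * Cinv)
    S = S + (mat.bulk_modulus * np.log(Je))[..., None, None] * Cinv

    for ai, bi, I4, v in (
        (mat.a_f, mat.b_f, state.I4fe, state.f),
        (mat.a_s, mat.b_s, state.I4se, state.s),
    ):
        e = I4 - 1.0
        if mat.tension_only:
            e = np.maximum(e, 0.0)
        g = 2.0 * ai * e * np.exp(bi * e**2)
        S = S + g[..., None, None] * (v[..., :, None] * v[..., None, :])

    g8 = mat.a_fs * state.I8fse * np.exp(mat.b_fs * state.I8fse**2)
    fs = state.f[..., :, None] * state.s[..., None, :]
    S = S + g8[..., None, None] * (fs + np.swapaxes(fs, -1, -2))
    return S


def pk2_stress(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Second Piola--Kirchhoff stress in the (pre-growth) reference frame.

    The elastic stress Se = 2 dpsi/dCe is pulled back through the growth
    tensor, S = det(Fg) Fg^-1 Se Fg^-T, so that S is work-conjugate to the
    total right Cauchy--Green tensor C: S = 2 d(det(Fg) psi)/dC.
    """
    Se = _pk2_elastic(state, mat)
    Fginv = np.linalg.inv(state.Fg)
    Jg = np.linalg.det(state.Fg)
    return Jg[..., None, None] * (Fginv @ Se @ np.swapaxes(Fginv, -1, -2))
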