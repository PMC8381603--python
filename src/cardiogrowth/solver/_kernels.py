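"""Numba-compiled inner kernels of the explicit solver.

These implement the hot per-increment work: total-Lagrangian internal
forces with the grown Holzapfel--Ogden response, follower pressure on
deformed facets, the St. Venant--Kirchhoff membrane pericardium and the
node-to-facet penalty contact.  The pure-numpy `constitutive` module is the
reference implementation; consistency between the two routes is asserted by
the energy-gradient oracles in the test suite.
"""

import numpy as np
from numba import njit

__all__ = ["internal_forces", "pressure_forces", "membrane_forces", "contact_forces"]


@njit(cache=True)
def _inv3(A, out):
    a, b, c = A[0, 0], A[0, 1], A[0, 2]
    d, e, f = A[1, 0], A[1, 1], A[1, 2]
    g, h, i = A[2, 0], A[2, 1], A[2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    out[0, 0] = (e * i - f * h) / det
    out[0, 1] = (c * h - b * i) / det
    out[0, 2] = (b * f - c * e) / det
    out[1, 0] = (f * g - d * i) / det
    out[1, 1] = (a * i - c * g) / det
    out[1, 2] = (c * d - a * f) / det
    out[2, 0] = (d * h - e * g) / det
    out[2, 1] = (b * g - a * h) / det
    out[2, 2] = (a * e - b * d) / det
    return det


@njit(cache=True)
def internal_forces(
    u,
    elements,
    dNdX,
    detJ,
    fvec,
    svec,
    alpha_f,
    alpha_n,
    a,
    b,
    a_f,
    b_f,
    a_s,
    b_s,
    a_fs,
    b_fs,
    kappa,
    tension_only,
    forces,
):
    """Accumulate internal nodal forces; return (strain energy, bad element).

    ``forces`` is added to in place (caller zeroes it).  The energy is the
    total strain energy in the reference volume, det(Fg) * psi integrated.
    The volumetric penalty uses mean dilatation (the element-averaged
    elastic Jacobian) to relieve the volumetric locking of fully integrated
    trilinear hexahedra.  The returned bad-element id is -1 when all
    deformation gradients are admissible (positive determinant), else the
    offending element.
    """
    ne = elements.shape[0]
    gf = 1.0 + alpha_f
    gn = 1.0 + alpha_n
    Jg = gf * gn * gn
    ci = 1.0 / gn
    cf = 1.0 / gf - 1.0 / gn

    F = np.empty((3, 3))
    Fs = np.empty((8, 3, 3))
    Finv = np.empty((3, 3))
    Jes = np.empty(8)
    Fe = np.empty((3, 3))
    Ce = np.empty((3, 3))
    Cinv = np.empty((3, 3))
    Se = np.empty((3, 3))
    S = np.empty((3, 3))
    P = np.empty((3, 3))
    Fginv = np.empty((3, 3))
    tmp = np.empty((3, 3))
    energy = 0.0
    bad = -1

    for e in range(ne):
        f0 = fvec[e]
        s0 = svec[e]
        for i in range(3):
            for j in range(3):
                Fginv[i, j] = cf * f0[i] * f0[j]
            Fginv[i, i] += ci
        # pass 1: deformation gradients and the element-mean elastic Jacobian
        Ve = 0.0
        Jbar = 0.0
        for g in range(8):
            for i in range(3):
                for j in range(3):
                    F[i, j] = 1.0 if i == j else 0.0
            for na in range(8):
                node = elements[e, na]
                for i in range(3):
                    ui = u[node, i]
                    F[i, 0] += ui * dNdX[e, g, na, 0]
                    F[i, 1] += ui * dNdX[e, g, na, 1]
                    F[i, 2] += ui * dNdX[e, g, na, 2]
            detF = (
                F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
            )
            if detF <= 0.0 or not np.isfinite(detF):
                bad = e
                return energy, bad
            for i in range(3):
                for j in range(3):
                    Fs[g, i, j] = F[i, j]
            Jes[g] = detF / Jg
            Ve += detJ[e, g]
            Jbar += detJ[e, g] * Jes[g]
        Jbar /= Ve
        lnJbar = np.log(Jbar)
        cvol = kappa * lnJbar / Jbar * Jg  # multiplies Je_g * F^-T per gp
        energy += 0.5 * kappa * lnJbar * lnJbar * Jg * Ve

        for g in range(8):
            for i in range(3):
                for j in range(3):
                    F[i, j] = Fs[g, i, j]
            _inv3(F, Finv)
            # elastic part
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += F[i, k] * Fginv[k, j]
                    Fe[i, j] = acc
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += Fe[k, i] * Fe[k, j]
                    Ce[i, j] = acc
            detC = _inv3(Ce, Cinv)
            Je = np.sqrt(detC)
            I1 = Ce[0, 0] + Ce[1, 1] + Ce[2, 2]
            # invariants along microstructure directions
            I4f = 0.0
            I4s = 0.0
            I8 = 0.0
            for i in range(3):
                cf_i = 0.0
                cs_i = 0.0
                for j in range(3):
                    cf_i += Ce[i, j] * f0[j]
                    cs_i += Ce[i, j] * s0[j]
                I4f += f0[i] * cf_i
                I4s += s0[i] * cs_i
                I8 += f0[i] * cs_i
            Jm23 = Je ** (-2.0 / 3.0)
            I1iso = Jm23 * I1
            expI1 = np.exp(b * (I1iso - 3.0))
            coef_iso = a * expI1 * Jm23

            e4f = I4f - 1.0
            e4s = I4s - 1.0
            if tension_only:
                if e4f < 0.0:
                    e4f = 0.0
                if e4s < 0.0:
                    e4s = 0.0
            expf = np.exp(b_f * e4f * e4f)
            exps = np.exp(b_s * e4s * e4s)
            exp8 = np.exp(b_fs * I8 * I8)
            gff = 2.0 * a_f * e4f * expf
            gss = 2.0 * a_s * e4s * exps
            g8 = a_fs * I8 * exp8

            # strain energy measured from the reference state (the constant
            # a/(2b) of the printed isotropic term is subtracted); the
            # volumetric part was accumulated element-wise above
            psi = (
                a / (2.0 * b) * (expI1 - 1.0)
                + a_f / (2.0 * b_f) * (expf - 1.0)
                + a_s / (2.0 * b_s) * (exps - 1.0)
                + a_fs / (2.0 * b_fs) * (exp8 - 1.0)
            )
            energy += Jg * psi * detJ[e, g]

            for i in range(3):
                for j in range(3):
                    Se[i, j] = (
                        coef_iso * ((1.0 if i == j else 0.0) - (I1 / 3.0) * Cinv[i, j])
                        + gff * f0[i] * f0[j]
                        + gss * s0[i] * s0[j]
                        + g8 * (f0[i] * s0[j] + s0[i] * f0[j])
                    )
            # pull back through the (symmetric) growth tensor: S = Jg Fginv Se Fginv
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += Fginv[i, k] * Se[k, j]
                    tmp[i, j] = acc
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += tmp[i, k] * Fginv[k, j]
                    S[i, j] = Jg * acc
            cv = cvol * Jes[g]
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += F[i, k] * S[k, j]
                    P[i, j] = acc + cv * Finv[j, i]
            w = detJ[e, g]
            for na in range(8):
                node = elements[e, na]
                for i in range(3):
                    forces[node, i] += w * (
                        P[i, 0] * dNdX[e, g, na, 0]
                        + P[i, 1] * dNdX[e, g, na, 1]
                        + P[i, 2] * dNdX[e, g, na, 2]
                    )
    return energy, bad


_QGP = 1.0 / np.sqrt(3.0)
_QUAD_GP = np.array([[-_QGP, -_QGP], [_QGP, -_QGP], [_QGP, _QGP], [-_QGP, _QGP]])
_QUAD_S = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
QUAD_N = 0.25 * (1 + _QUAD_GP[:, None, 0] * _QUAD_S[None, :, 0]) * (
    1 + _QUAD_GP[:, None, 1] * _QUAD_S[None, :, 1]
)  # (4 gp, 4 nodes)
QUAD_DN = np.empty((4, 4, 2))
QUAD_DN[:, :, 0] = 0.25 * _QUAD_S[None, :, 0] * (1 + _QUAD_GP[:, None, 1] * _QUAD_S[None, :, 1])
QUAD_DN[:, :, 1] = 0.25 * _QUAD_S[None, :, 1] * (1 + _QUAD_GP[:, None, 0] * _QUAD_S[None, :, 0])


@njit(cache=True)
def pressure_forces(x, quads, p, N, dN, forces):
    """Follower pressure on deformed quad facets (outward-oriented normals).

    The applied traction is -p n_out, i.e. a positive cavity pressure on the
    endocardium (whose outward normal points into the cavity) inflates the
    wall.  Forces are accumulated into ``forces`` in place.
    """
    if p == 0.0:
        return
    nf = quads.shape[0]
    for q in range(nf):
        for g in range(4):
            t1x = t1y = t1z = 0.0
            t2x = t2y = t2z = 0.0
            for na in range(4):
                node = quads[q, na]
                t1x += dN[g, na, 0] * x[node, 0]
                t1y += dN[g, na, 0] * x[node, 1]
                t1z += dN[g, na, 0] * x[node, 2]
                t2x += dN[g, na, 1] * x[node, 0]
                t2y += dN[g, na, 1] * x[node, 1]
                t2z += dN[g, na, 1] * x[node, 2]
            nx = t1y * t2z - t1z * t2y
            ny = t1z * t2x - t1x * t2z
            nz = t1x * t2y - t1y * t2x
            for na in range(4):
                node = quads[q, na]
                w = p * N[g, na]
                forces[node, 0] -= w * nx
                forces[node, 1] -= w * ny
                forces[node, 2] -= w * nz


@njit(cache=True)
def membrane_forces(x, quads, dN, Aref, Tinv, wA, lam, mu, thickness, forces, tension_only):
    """Total-Lagrangian St. Venant--Kirchhoff membrane internal forces.

    ``Aref`` is the covariant reference metric, ``Tinv`` the inverse of the
    map from local coordinates to a reference-tangent orthonormal frame and
    ``wA`` the reference area element, per facet and Gauss point.  ``lam``
    is the plane-stress Lame parameter E nu/(1-nu^2), ``mu`` the shear
    modulus.  With ``tension_only`` the membrane carries no compressive
    principal stress (tension-field / wrinkling model), which removes the
    mesh-dependent compressive buckling of a bending-free membrane.
    Returns the membrane strain energy.
    """
    nf = quads.shape[0]
    energy = 0.0
    g1 = np.empty(3)
    g2 = np.empty(3)
    for q in range(nf):
        for g in range(4):
            for i in range(3):
                g1[i] = 0.0
                g2[i] = 0.0
            for na in range(4):
                node = quads[q, na]
                for i in range(3):
                    g1[i] += dN[g, na, 0] * x[node, i]
                    g2[i] += dN[g, na, 1] * x[node, i]
            a11 = g1[0] * g1[0] + g1[1] * g1[1] + g1[2] * g1[2]
            a22 = g2[0] * g2[0] + g2[1] * g2[1] + g2[2] * g2[2]
            a12 = g1[0] * g2[0] + g1[1] * g2[1] + g1[2] * g2[2]
            # covariant Green strain
            E11 = 0.5 * (a11 - Aref[q, g, 0, 0])
            E22 = 0.5 * (a22 - Aref[q, g, 1, 1])
            E12 = 0.5 * (a12 - Aref[q, g, 0, 1])
            # Cartesian strain in the reference tangent frame:
            # E_c = Tinv^T E_cov Tinv
            p11 = Tinv[q, g, 0, 0]
            p12 = Tinv[q, g, 0, 1]
            p21 = Tinv[q, g, 1, 0]
            p22 = Tinv[q, g, 1, 1]
            b11 = E11 * p11 + E12 * p21
            b12 = E11 * p12 + E12 * p22
            b21 = E12 * p11 + E22 * p21
            b22 = E12 * p12 + E22 * p22
            Ec11 = p11 * b11 + p21 * b21
            Ec12 = p11 * b12 + p21 * b22
            Ec22 = p12 * b12 + p22 * b22
            trE = Ec11 + Ec22
            Sc11 = lam * trE + 2.0 * mu * Ec11
            Sc22 = lam * trE + 2.0 * mu * Ec22
            Sc12 = 2.0 * mu * Ec12
            if tension_only:
                sm = 0.5 * (Sc11 + Sc22)
                sr = np.sqrt(0.25 * (Sc11 - Sc22) ** 2 + Sc12 * Sc12)
                l1 = sm + sr
                l2 = sm - sr
                if l1 <= 0.0:
                    Sc11 = Sc22 = Sc12 = 0.0
                elif l2 < 0.0:
                    # keep only the tensile principal component
                    vx = Sc12
                    vy = l1 - Sc11
                    vn = np.sqrt(vx * vx + vy * vy)
                    if vn < 1e-30:
                        vx, vy = 1.0, 0.0
                    else:
                        vx /= vn
                        vy /= vn
                    Sc11 = l1 * vx * vx
                    Sc12 = l1 * vx * vy
                    Sc22 = l1 * vy * vy
            # back to contravariant components: S^ab = Tinv S_c Tinv^T
            c11 = p11 * Sc11 + p12 * Sc12
            c12 = p11 * Sc12 + p12 * Sc22
            c21 = p21 * Sc11 + p22 * Sc12
            c22 = p21 * Sc12 + p22 * Sc22
            S11 = c11 * p11 + c12 * p12
            S12 = c11 * p21 + c12 * p22
            S22 = c21 * p21 + c22 * p22
            w = thickness * wA[q, g]
            energy += 0.5 * w * (Sc11 * Ec11 + Sc22 * Ec22 + 2.0 * Sc12 * Ec12)
            for na in range(4):
                node = quads[q, na]
                d1 = dN[g, na, 0]
                d2 = dN[g, na, 1]
                for i in range(3):
                    forces[node, i] += w * (
                        S11 * d1 * g1[i]
                        + S22 * d2 * g2[i]
                        + S12 * (d1 * g2[i] + d2 * g1[i])
                    )
    return energy


@njit(cache=True)
def contact_forces(
    x_lv, epi_nodes, trib, x_sh, sh_quads, near_facet, slope, f_lv, f_sh,
    v_lv, v_sh, m_lv, m_sh, damping_xi,
):
    """Frictionless node-to-facet penalty contact, p = slope * overclosure.

    For each epicardial node the signed gap h to its candidate pericardial
    facet is measured along the facet normal (oriented away from the LV);
    h > 0 means penetration.  Equal-and-opposite normal forces (pressure x
    tributary area) are applied to the node and, via bilinear weights at
    the projection point, to the facet nodes.  When velocities and nodal
    masses are supplied, a normal dashpot at fraction ``damping_xi`` of
    critical (w.r.t. the local penalty stiffness and reduced mass)
    suppresses contact chatter.  Returns the penalty energy.
    """
    energy = 0.0
    with_damping = damping_xi > 0.0
    for k in range(epi_nodes.shape[0]):
        q = near_facet[k]
        if q < 0:
            continue
        node = epi_nodes[k]
        x0 = sh_quads[q, 0]
        x1 = sh_quads[q, 1]
        x2 = sh_quads[q, 2]
        x3 = sh_quads[q, 3]
        # closest-point projection onto the (possibly warped) bilinear
        # patch: a few Newton steps in the local coordinates, clamped to
        # the facet.  A node resting anywhere on a conforming curved shell
        # then reads h = 0 exactly (no chord-sag false penetration).
        xi = 0.0
        eta = 0.0
        px = py = pz = 0.0
        t1x = t1y = t1z = t2x = t2y = t2z = 0.0
        for _ in range(4):
            w0 = 0.25 * (1 - xi) * (1 - eta)
            w1 = 0.25 * (1 + xi) * (1 - eta)
            w2 = 0.25 * (1 + xi) * (1 + eta)
            w3 = 0.25 * (1 - xi) * (1 + eta)
            px = w0 * x_sh[x0, 0] + w1 * x_sh[x1, 0] + w2 * x_sh[x2, 0] + w3 * x_sh[x3, 0]
            py = w0 * x_sh[x0, 1] + w1 * x_sh[x1, 1] + w2 * x_sh[x2, 1] + w3 * x_sh[x3, 1]
            pz = w0 * x_sh[x0, 2] + w1 * x_sh[x1, 2] + w2 * x_sh[x2, 2] + w3 * x_sh[x3, 2]
            t1x = 0.25 * ((1 - eta) * (x_sh[x1, 0] - x_sh[x0, 0]) + (1 + eta) * (x_sh[x2, 0] - x_sh[x3, 0]))
            t1y = 0.25 * ((1 - eta) * (x_sh[x1, 1] - x_sh[x0, 1]) + (1 + eta) * (x_sh[x2, 1] - x_sh[x3, 1]))
            t1z = 0.25 * ((1 - eta) * (x_sh[x1, 2] - x_sh[x0, 2]) + (1 + eta) * (x_sh[x2, 2] - x_sh[x3, 2]))
            t2x = 0.25 * ((1 - xi) * (x_sh[x3, 0] - x_sh[x0, 0]) + (1 + xi) * (x_sh[x2, 0] - x_sh[x1, 0]))
            t2y = 0.25 * ((1 - xi) * (x_sh[x3, 1] - x_sh[x0, 1]) + (1 + xi) * (x_sh[x2, 1] - x_sh[x1, 1]))
            t2z = 0.25 * ((1 - xi) * (x_sh[x3, 2] - x_sh[x0, 2]) + (1 + xi) * (x_sh[x2, 2] - x_sh[x1, 2]))
            dx = x_lv[node, 0] - px
            dy = x_lv[node, 1] - py
            dz = x_lv[node, 2] - pz
            a11 = t1x * t1x + t1y * t1y + t1z * t1z
            a22 = t2x * t2x + t2y * t2y + t2z * t2z
            a12 = t1x * t2x + t1y * t2y + t1z * t2z
            det = a11 * a22 - a12 * a12
            if det < 1e-30:
                break
            r1 = dx * t1x + dy * t1y + dz * t1z
            r2 = dx * t2x + dy * t2y + dz * t2z
            xi += (a22 * r1 - a12 * r2) / det
            eta += (a11 * r2 - a12 * r1) / det
            if xi > 1.0:
                xi = 1.0
            elif xi < -1.0:
                xi = -1.0
            if eta > 1.0:
                eta = 1.0
            elif eta < -1.0:
                eta = -1.0
        nx = t1y * t2z - t1z * t2y
        ny = t1z * t2x - t1x * t2z
        nz = t1x * t2y - t1y * t2x
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-30:
            continue
        nx /= nn
        ny /= nn
        nz /= nn
        w0 = 0.25 * (1 - xi) * (1 - eta)
        w1 = 0.25 * (1 + xi) * (1 - eta)
        w2 = 0.25 * (1 + xi) * (1 + eta)
        w3 = 0.25 * (1 - xi) * (1 + eta)
        px = w0 * x_sh[x0, 0] + w1 * x_sh[x1, 0] + w2 * x_sh[x2, 0] + w3 * x_sh[x3, 0]
        py = w0 * x_sh[x0, 1] + w1 * x_sh[x1, 1] + w2 * x_sh[x2, 1] + w3 * x_sh[x3, 1]
        pz = w0 * x_sh[x0, 2] + w1 * x_sh[x1, 2] + w2 * x_sh[x2, 2] + w3 * x_sh[x3, 2]
        h = (x_lv[node, 0] - px) * nx + (x_lv[node, 1] - py) * ny + (x_lv[node, 2] - pz) * nz
        if h <= 0.0:
            continue
        p = slope * h
        fmag = p * trib[k]
        energy += 0.5 * slope * h * h * trib[k]
        ftx = fty = ftz = 0.0
        if with_damping:
            msh_avg = 0.25 * (m_sh[x0] + m_sh[x1] + m_sh[x2] + m_sh[x3])
            m_red = m_lv[node] * msh_avg / (m_lv[node] + msh_avg)
            dcoef = 2.0 * damping_xi * np.sqrt(slope * trib[k] * m_red)
            vsx = 0.25 * (v_sh[x0, 0] + v_sh[x1, 0] + v_sh[x2, 0] + v_sh[x3, 0])
            vsy = 0.25 * (v_sh[x0, 1] + v_sh[x1, 1] + v_sh[x2, 1] + v_sh[x3, 1])
            vsz = 0.25 * (v_sh[x0, 2] + v_sh[x1, 2] + v_sh[x2, 2] + v_sh[x3, 2])
            vrx = v_lv[node, 0] - vsx
            vry = v_lv[node, 1] - vsy
            vrz = v_lv[node, 2] - vsz
            vreln = vrx * nx + vry * ny + vrz * nz
            fmag += dcoef * vreln  # positive v_rel.n = deepening penetration
            if fmag < 0.0:
                fmag = 0.0  # no adhesion: the dashpot never pulls
            # tangential viscosity: pressure on a curved surface gives the
            # sliding node negative tangential stiffness (~ -pA/R) that a
            # normal-only dashpot cannot stabilize; pure drag vanishes in
            # statics, so equilibria remain frictionless
            ftx = dcoef * (vrx - vreln * nx)
            fty = dcoef * (vry - vreln * ny)
            ftz = dcoef * (vrz - vreln * nz)
        f_lv[node, 0] -= fmag * nx + ftx
        f_lv[node, 1] -= fmag * ny + fty
        f_lv[node, 2] -= fmag * nz + ftz
        f_sh[x0, 0] += w0 * (fmag * nx + ftx)
        f_sh[x0, 1] += w0 * (fmag * ny + fty)
        f_sh[x0, 2] += w0 * (fmag * nz + ftz)
        f_sh[x1, 0] += w1 * (fmag * nx + ftx)
        f_sh[x1, 1] += w1 * (fmag * ny + fty)
        f_sh[x1, 2] += w1 * (fmag * nz + ftz)
        f_sh[x2, 0] += w2 * (fmag * nx + ftx)
        f_sh[x2, 1] += w2 * (fmag * ny + fty)
        f_sh[x2, 2] += w2 * (fmag * nz + ftz)
        f_sh[x3, 0] += w3 * (fmag * nx + ftx)
        f_sh[x3, 1] += w3 * (fmag * ny + fty)
        f_sh[x3, 2] += w3 * (fmag * nz + ftz)
    return energy
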