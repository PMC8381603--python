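"""Growth tensor and Holzapfel--Ogden energy/stress identities."""

import numpy as np
import pytest

from cardiogrowth.constitutive import (
    DeformationState,
    GrowthParams,
    MaterialParams,
    growth_tensor,
    pk2_stress,
    reference_energy,
    strain_energy,
)

from conftest import random_states


class TestGrowthTensor:
    def test_zero_growth_is_identity(self):
        Fg = growth_tensor(GrowthParams(0.0, 0.0), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(Fg, np.eye(3))

    def test_pure_fiber_growth_along_x(self):
        Fg = growth_tensor(GrowthParams(1.0, 0.0), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(Fg, np.diag([2.0, 1.0, 1.0]))

    def test_printed_determinant_example(self):
        Fg = growth_tensor(GrowthParams(0.9, 0.3), np.array([1.0, 0.0, 0.0]))
        assert np.linalg.det(Fg) == pytest.approx(1.9 * 1.3**2, abs=1e-12)

    def test_determinant_identity_random_parameters(self):
        """det Fg = (1+alpha_f)(1+alpha_n)^2 exactly, any direction."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            af, an = rng.uniform(0, 1, 2)
            f = rng.standard_normal(3)
            f /= np.linalg.norm(f)
            Fg = growth_tensor(GrowthParams(af, an), f)
            assert np.linalg.det(Fg) == pytest.approx((1 + af) * (1 + an) ** 2, rel=1e-12)
            w = np.sort(np.linalg.eigvalsh(Fg))
            np.testing.assert_allclose(w, np.sort([1 + af, 1 + an, 1 + an]), rtol=1e-12)


class TestStrainEnergy:
    def test_reference_state_energy_and_invariants(self, material):
        f = np.array([1.0, 0.0, 0.0])
        s = np.array([0.0, 1.0, 0.0])
        st = DeformationState.make(np.eye(3), GrowthParams(0, 0), f, s)
        assert st.I1e == pytest.approx(3.0)
        assert st.I4fe == pytest.approx(1.0)
        assert st.I8fse == pytest.approx(0.0)
        # only the constant isotropic offset a/(2b) remains
        assert strain_energy(st, material) == pytest.approx(material.a / (2 * material.b))

    def test_uniaxial_stretch_matches_hand_computed_invariants(self, material):
        lam = 1.1
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        f = np.array([1.0, 0.0, 0.0])
        s = np.array([0.0, 1.0, 0.0])
        st = DeformationState.make(F, GrowthParams(0, 0), f, s)
        I1 = lam**2 + 2.0 / lam
        I4f = lam**2
        I4s = 1.0 / lam
        psi_hand = (
            material.a / (2 * material.b) * np.exp(material.b * (I1 - 3))
            + material.a_f / (2 * material.b_f) * (np.exp(material.b_f * (I4f - 1) ** 2) - 1)
            # sheet term inactive in compression (tension-only), I4s < 1
        )
        assert np.linalg.det(F) == pytest.approx(1.0)
        assert strain_energy(st, material) == pytest.approx(psi_hand, rel=1e-12)
        assert I4s < 1.0

    def test_frame_indifference(self, material):
        rng = np.random.default_rng(3)
        F, f, s = random_states(20, rng)
        st = DeformationState.make(F, GrowthParams(0.2, 0.1), f, s)
        psi = strain_energy(st, material)
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(20, random_state=5).as_matrix()
        stQ = DeformationState.make(Q @ F, GrowthParams(0.2, 0.1), f, s)
        np.testing.assert_allclose(strain_energy(stQ, material), psi, rtol=1e-10)

    def test_energy_increases_along_stretch_rays(self, material):
        """psi grows monotonically moving away from the reference along
        random deformation rays."""
        rng = np.random.default_rng(11)
        D = 0.3 * rng.standard_normal((10, 3, 3))
        f = np.array([1.0, 0.0, 0.0])
        s = np.array([0.0, 1.0, 0.0])
        for Di in D:
            last = 0.0
            for t in (0.02, 0.05, 0.1, 0.2):
                F = np.eye(3) + t * Di
                if np.linalg.det(F) <= 0.1:
                    break
                st = DeformationState.make(F, GrowthParams(0, 0), f, s)
                psi = float(strain_energy(st, material)) - material.a / (2 * material.b)
                assert psi > last - 1e-14
                last = psi


class TestPK2Stress:
    def test_stress_free_reference(self, material):
        f = np.array([1.0, 0.0, 0.0])
        s = np.array([0.0, 1.0, 0.0])
        st = DeformationState.make(np.eye(3), GrowthParams(0, 0), f, s)
        assert np.abs(pk2_stress(st, material)).max() < 1e-12

    def test_compatible_growth_is_stress_free(self, material):
        """F = Fg (pure growth absorbed kinematically) leaves Fe = I and a
        vanishing stress at any growth level."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            af, an = rng.uniform(0, 1, 2)
            f = rng.standard_normal(3)
            f /= np.linalg.norm(f)
            tmp = rng.standard_normal(3)
            s = tmp - tmp @ f * f
            s /= np.linalg.norm(s)
            g = GrowthParams(af, an)
            st = DeformationState.make(growth_tensor(g, f), g, f, s)
            assert np.abs(pk2_stress(st, material)).max() < 1e-10

    def test_finite_difference_energy_consistency(self, material):
        """S agrees with central differences of det(Fg) psi w.r.t. C at
        relative tolerance 1e-5 over 50 random states."""
        rng = np.random.default_rng(0)
        F, f, s = random_states(50, rng)
        g = GrowthParams(0.3, 0.15)
        S = pk2_stress(DeformationState.make(F, g, f, s), material)
        P = F @ S  # first PK, FD-checked through F perturbations
        h = 1e-6
        P_fd = np.zeros_like(F)
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[:, i, j] += h
                Fm[:, i, j] -= h
                ep = reference_energy(DeformationState.make(Fp, g, f, s), material)
                em = reference_energy(DeformationState.make(Fm, g, f, s), material)
                P_fd[:, i, j] = (ep - em) / (2 * h)
        scale = np.abs(P).max()
        assert np.abs(P - P_fd).max() / scale < 1e-5

    def test_isotropic_limit_objectivity(self):
        """With the anisotropic moduli off, stress of a rotated deformation
        is the rotated stress (isotropy)."""
        mat = MaterialParams().isotropic()
        rng = np.random.default_rng(9)
        F, f, s = random_states(10, rng)
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(10, random_state=4).as_matrix()
        g = GrowthParams(0, 0)
        S = pk2_stress(DeformationState.make(F, g, f, s), mat)
        SQ = pk2_stress(DeformationState.make(F @ Q, g, f, s), mat)
        # material rotation Q: S(FQ) = Q^T S(F) Q for an isotropic solid
        np.testing.assert_allclose(SQ, np.swapaxes(Q, 1, 2) @ S @ Q, rtol=1e-8, atol=1e-10)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        af=st.floats(0.0, 1.0),
        an=st.floats(0.0, 1.0),
        phi=st.floats(0.0, 2 * np.pi),
        costh=st.floats(-1.0, 1.0),
    )
    def test_growth_tensor_spectrum_property(af, an, phi, costh):
        """For any parameters and fiber direction the growth tensor is
        symmetric with eigenvalues {1+alpha_f, 1+alpha_n, 1+alpha_n} and
        f as the 1+alpha_f eigenvector."""
        sinth = np.sqrt(max(0.0, 1.0 - costh**2))
        f = np.array([sinth * np.cos(phi), sinth * np.sin(phi), costh])
        Fg = growth_tensor(GrowthParams(af, an), f)
        np.testing.assert_allclose(Fg, Fg.T, atol=1e-14)
        np.testing.assert_allclose(Fg @ f, (1 + af) * f, atol=1e-12)
        w = np.sort(np.linalg.eigvalsh(Fg))
        np.testing.assert_allclose(w, np.sort([1 + af, 1 + an, 1 + an]), atol=1e-12)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_material_validation():
    with pytest.raises(ValueError):
        MaterialParams(bulk_modulus=10.0).validate()
    with pytest.raises(ValueError):
        GrowthParams(1.5, 0.0).validate()
    MaterialParams().validate()
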