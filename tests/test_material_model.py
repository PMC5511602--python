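"""GOH hyper-viscoelastic material: invariants, energy, stress, relaxation."""

import numpy as np
import pytest

from axonvar import material_model as mm
from axonvar import synthetic_data as sd

EX = np.array([1.0, 0.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


def uniaxial_state(lam=1.1, fiber=EX):
    return mm.kinematics(np.diag([lam, lam**-0.5, lam**-0.5]), fiber)


def random_rotation(rng):
    Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestKinematics:
    def test_identity(self):
        st = mm.kinematics(np.eye(3), EZ)
        assert st.J == 1.0
        assert st.I1_iso == pytest.approx(3.0, abs=1e-15)
        assert st.I4_iso == pytest.approx(1.0, abs=1e-15)

    def test_uniaxial_closed_form(self):
        lam = 1.1
        st = uniaxial_state(lam)
        assert st.J == pytest.approx(1.0, abs=1e-14)
        assert st.I1_iso == pytest.approx(lam**2 + 2.0 / lam, abs=1e-12)
        assert st.I4_iso == pytest.approx(lam**2, abs=1e-12)
        assert abs(np.linalg.det(st.C_iso) - 1.0) < 1e-10

    def test_pure_rotation_is_invariant(self):
        Q = random_rotation(np.random.default_rng(0))
        st = mm.kinematics(Q, EZ)
        assert st.I1_iso == pytest.approx(3.0, abs=1e-12)
        assert st.I4_iso == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mm.kinematics(-np.eye(3), EZ)
        with pytest.raises(ValueError):
            mm.kinematics(np.eye(3), np.array([1.0, 1.0, 0.0]))


class TestAxonalStrain:
    def test_zero_at_identity(self):
        assert mm.axonal_strain(mm.kinematics(np.eye(3), EZ), 0.2) == 0.0

    def test_uniaxial_fully_aligned(self):
        assert mm.axonal_strain(uniaxial_state(1.1), 0.0) == pytest.approx(0.21, abs=1e-12)

    def test_uniaxial_dispersed(self):
        """k = 0.2732 blends the isotropic and fiber contributions."""
        st = uniaxial_state(1.1)
        expected = 0.2732 * (st.I1_iso - 3.0) + (1 - 3 * 0.2732) * (st.I4_iso - 1.0)
        got = mm.axonal_strain(st, 0.2732)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx(0.0456, abs=5e-5)

    def test_isotropic_limit_independent_of_fiber(self):
        rng = np.random.default_rng(4)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        values = []
        for _ in range(10):
            n0 = rng.normal(size=3)
            n0 /= np.linalg.norm(n0)
            values.append(mm.axonal_strain(mm.kinematics(F, n0), 1.0 / 3.0))
        assert np.ptp(values) < 1e-12


class TestStrainEnergy:
    def test_zero_at_identity(self):
        p = mm.MaterialParams(k=0.1)
        assert mm.strain_energy(mm.kinematics(np.eye(3), EZ), p) == 0.0

    def test_pure_volumetric_closed_form(self):
        """Only the bulk term survives: K((J^2-1)/4 - ln(J)/2) at J = 1.2."""
        st = mm.kinematics(np.eye(3) * 1.2 ** (1.0 / 3.0), EZ)
        p = mm.MaterialParams(k=1.0 / 3.0, K=50e6)
        expected = 50e6 * ((1.2**2 - 1) / 4 - 0.5 * np.log(1.2))
        W = mm.strain_energy(st, p)
        assert W == pytest.approx(expected, rel=1e-12)
        assert W == pytest.approx(9.4195e5, rel=2e-5)

    def test_fiber_in_compression_contributes_nothing(self):
        lam = 0.9  # fiber shortens: Macaulay bracket kills the fiber term
        st = uniaxial_state(lam)
        with_fibers = mm.MaterialParams(k=0.0, k1=1e4, k2=1.0)
        without = mm.MaterialParams(k=0.0, k1=0.0, k2=0.0)
        assert mm.strain_energy(st, with_fibers) == mm.strain_energy(st, without)

    def test_k2_limit_continuity(self):
        st = uniaxial_state(1.08)
        W_limit = mm.strain_energy(st, mm.MaterialParams(k=0.05, k1=200.0, k2=0.0))
        W_small = mm.strain_energy(st, mm.MaterialParams(k=0.05, k1=200.0, k2=1e-6))
        assert abs(W_small - W_limit) / W_limit < 1e-6

    def test_objectivity(self):
        rng = np.random.default_rng(8)
        F = np.eye(3) + 0.15 * rng.normal(size=(3, 3))
        Q = random_rotation(rng)
        p = mm.MaterialParams(k=0.1, k1=150.0, k2=0.3)
        W1 = mm.strain_energy(mm.kinematics(F, EX), p)
        W2 = mm.strain_energy(mm.kinematics(Q @ F, EX), p)
        assert W2 == pytest.approx(W1, rel=1e-12)


class TestCauchyStress:
    def test_zero_at_identity(self):
        p = mm.MaterialParams(k=0.15, k1=100.0)
        sigma = mm.cauchy_stress(mm.kinematics(np.eye(3), EZ), p)
        assert np.abs(sigma).max() < 1e-9

    def test_matches_numerical_energy_derivative(self):
        """sigma = J^-1 (dW/dF) F^T against central differences, 100 states."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 100:
            F = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
            if np.linalg.det(F) < 0.3:
                continue
            n0 = rng.normal(size=3)
            n0 /= np.linalg.norm(n0)
            p = mm.MaterialParams(
                k=rng.uniform(0, 1 / 3), k1=100.0, k2=float(rng.choice([0.0, 0.5]))
            )
            sigma = mm.cauchy_stress(mm.kinematics(F, n0), p)
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (
                        mm.strain_energy(mm.kinematics(Fp, n0), p)
                        - mm.strain_energy(mm.kinematics(Fm, n0), p)
                    ) / (2 * h)
            sigma_num = P @ F.T / np.linalg.det(F)
            sigma_num = 0.5 * (sigma_num + sigma_num.T)
            scale = max(np.abs(sigma_num).max(), 1.0)
            assert np.abs(sigma - sigma_num).max() / scale < 1e-5
            checked += 1

    def test_objectivity_transformation(self):
        rng = np.random.default_rng(21)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        Q = random_rotation(rng)
        p = mm.MaterialParams(k=0.1, k1=100.0)
        s1 = mm.cauchy_stress(mm.kinematics(F, EX), p)
        s2 = mm.cauchy_stress(mm.kinematics(Q @ F, EX), p)
        assert np.abs(s2 - Q @ s1 @ Q.T).max() < 1e-6 * max(np.abs(s1).max(), 1.0)


class TestViscoelasticity:
    def test_brain_prony_partition_of_unity(self):
        p = mm.BRAIN_PRONY
        assert abs(p.m_inf + p.moduli.sum() - 1.0) < 1e-12
        assert p.g(np.array([0.0]))[0] == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ValueError, match="M_inf"):
            mm.PronySeries(moduli=[0.5], taus=[1e-3], m_inf=0.3)

    def test_elastic_limit_equals_instantaneous(self):
        hist = sd.make_deformation_history("simple_shear", 0.4, fiber_dir0=EX)
        p = mm.MaterialParams(k=0.1, k1=100.0, prony=mm.ELASTIC)
        sig = mm.viscoelastic_stress(hist, p)
        for t in range(len(hist.times)):
            inst = mm.cauchy_stress(mm.kinematics(hist.F[t], EX), p)
            assert np.abs(sig[t] - inst).max() < 1e-9 * max(np.abs(inst).max(), 1.0)

    def test_step_strain_relaxes_to_long_term_modulus(self):
        """Held shear long past the slowest time relaxes the isochoric
        stress to M_inf times its instantaneous value (shear has J = 1,
        so there is no volumetric contribution)."""
        gamma = 0.2
        dt = 1e-3
        times = np.arange(0.0, 1.0 + dt / 2, dt)
        F = np.tile(np.eye(3), (len(times), 1, 1))
        F[1:, 0, 1] = gamma  # step applied in the first interval, then held
        hist = sd.DeformationHistory(times=times, F=F, fiber_dir0=EX)
        p = mm.MaterialParams(k=0.2, k1=100.0)
        sig = mm.viscoelastic_stress(hist, p)
        inst = mm.cauchy_stress(mm.kinematics(F[-1], EX), p)
        assert np.abs(sig[-1] - p.prony.m_inf * inst).max() < 0.01 * np.abs(inst).max()

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            sd.DeformationHistory(times=[0.0, 2.0, 1.0], F=np.tile(np.eye(3), (3, 1, 1)))


class TestEvaluateHistory:
    def test_identity_history_has_zero_peaks(self):
        times = np.array([0.0, 1e-3, 2e-3])
        hist = sd.DeformationHistory(times=times, F=np.tile(np.eye(3), (3, 1, 1)))
        res = mm.evaluate_history(hist, mm.MaterialParams(k=0.1))
        assert res.mas == 0.0
        assert res.mps == pytest.approx(0.0, abs=1e-15)

    def test_uniaxial_ramp_closed_forms(self):
        hist = sd.make_deformation_history("uniaxial_isochoric", 1.1, fiber_dir0=EX)
        res = mm.evaluate_history(hist, mm.MaterialParams(k=0.0))
        lam = 1.1
        assert res.mas == pytest.approx(lam**2 - 1.0, abs=1e-12)  # I4 - 1 at k = 0
        assert res.mas == pytest.approx(0.21, abs=1e-12)
        assert res.mps == pytest.approx((lam**2 - 1) / 2, abs=1e-12)
        assert res.mps == pytest.approx(0.105, abs=1e-12)
        # monotone ramp peaks at the final step
        assert res.axonal_strain.argmax() == len(hist.times) - 1

    def test_gray_matter_mas_independent_of_fiber_direction(self):
        hist = sd.make_deformation_history("simple_shear", 0.3)
        p = mm.MaterialParams(k=1.0 / 3.0)
        rng = np.random.default_rng(6)
        peaks = []
        for _ in range(10):
            n0 = rng.normal(size=3)
            n0 /= np.linalg.norm(n0)
            peaks.append(mm.evaluate_history(hist, p, fiber_dir=n0).mas)
        assert np.ptp(peaks) < 1e-12

    def test_compressive_history_gives_zero_mas(self):
        # the history starts at the identity, so the all-time maximum of the
        # axonal strain can never drop below the initial zero
        hist = sd.make_deformation_history("uniaxial_isochoric", 0.9, fiber_dir0=EX)
        res = mm.evaluate_history(hist, mm.MaterialParams(k=0.0))
        assert res.mas == 0.0
        assert not res.mas_clamped
        assert res.axonal_strain[-1] < 0
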