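"""Constitutive-law tests: energy/stress consistency, frame objectivity,
shear-rig symmetries and the 1-D exponential laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosim.materials import (
    SHEAR_MODES,
    ActiveLaw,
    DeformationState,
    ExpLaw1D,
    MaterialParamsHO,
    StressStrainCurve,
    active_tension,
    cauchy_stress,
    shear_test,
    strain_energy,
    stress_1d,
)

PRINTED = MaterialParamsHO()


def random_admissible_F(rng, scale=0.15):
    """Random deformation gradient near identity with positive determinant."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.2:
            return F


def fd_first_pk(params, F, h=1e-6):
    """Finite-difference dPsi/dF as the stress oracle."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (
                strain_energy(params, DeformationState(F=Fp))
                - strain_energy(params, DeformationState(F=Fm))
            ) / (2 * h)
    return P


class TestStrainEnergy:
    def test_zero_at_identity(self):
        assert strain_energy(PRINTED, DeformationState(F=np.eye(3))) == 0.0

    def test_zero_under_pure_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            assert strain_energy(PRINTED, DeformationState(F=R)) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_matches_term_by_term_evaluation(self):
        # F = diag(lam, lam^-1/2, lam^-1/2), lam = 1.1: hand evaluation of
        # each term of the energy with the printed parameter set
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        I1 = lam**2 + 2.0 / lam
        I4f = lam**2
        expected = 0.33 / (2 * 7.08) * np.expm1(7.08 * (I1 - 3.0))
        expected += 0.25 / (2 * 5.34) * np.expm1(5.34 * (I4f - 1.0) ** 2)
        assert strain_energy(PRINTED, DeformationState(F=F)) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_on_random_states(self, rng):
        for _ in range(50):
            F = random_admissible_F(rng)
            assert strain_energy(PRINTED, DeformationState(F=F)) >= 0.0

    def test_zero_scale_term_contributes_exactly_zero(self):
        # exponent of a zero-scale term is irrelevant (no 0/0)
        with_junk_exponents = PRINTED.replace(b_ss=0.0, b_fs=0.0)
        F = np.diag([1.2, 1.0, 1.0 / 1.2])
        s = DeformationState(F=F)
        assert strain_energy(with_junk_exponents, s) == strain_energy(PRINTED, s)

    def test_fiber_term_tension_only(self):
        # fiber compression (I4f < 1): the a_ff term must contribute nothing
        lam = 0.9
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        s = DeformationState(F=F)
        no_fiber = PRINTED.replace(a_ff=0.0)
        assert strain_energy(PRINTED, s) == pytest.approx(strain_energy(no_fiber, s), rel=1e-14)
        sigma_full = cauchy_stress(PRINTED, s)
        sigma_nof = cauchy_stress(no_fiber, s)
        np.testing.assert_allclose(sigma_full, sigma_nof, atol=1e-14)

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            DeformationState(F=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            DeformationState(F=np.eye(3), f0=np.array([1.0, 1.0, 0.0]))


class TestCauchyStress:
    def test_zero_at_identity(self):
        sigma = cauchy_stress(PRINTED, DeformationState(F=np.eye(3)))
        np.testing.assert_allclose(sigma, 0.0, atol=1e-14)

    def test_matches_energy_finite_difference(self, rng):
        # stress-energy consistency over random admissible states
        for _ in range(100):
            F = random_admissible_F(rng)
            state = DeformationState(F=F)
            sigma = cauchy_stress(PRINTED, state)
            sigma_fd = fd_first_pk(PRINTED, F) @ F.T / np.linalg.det(F)
            sigma_fd = 0.5 * (sigma_fd + sigma_fd.T)
            np.testing.assert_allclose(sigma, sigma_fd, rtol=1e-4, atol=1e-6)

    def test_fn_shear_stress_matches_finite_difference(self):
        g = 0.2
        F = np.eye(3)
        F[2, 0] = g  # FN mode: fiber lines sheared toward the normal axis
        state = DeformationState(F=F)
        sigma = cauchy_stress(PRINTED, state)
        sigma_fd = fd_first_pk(PRINTED, F) @ F.T / np.linalg.det(F)
        np.testing.assert_allclose(sigma, 0.5 * (sigma_fd + sigma_fd.T), rtol=1e-5)

    def test_objectivity_under_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(10):
            F = random_admissible_F(rng)
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            s1 = cauchy_stress(PRINTED, DeformationState(F=R @ F))
            s0 = cauchy_stress(PRINTED, DeformationState(F=F))
            np.testing.assert_allclose(s1, R @ s0 @ R.T, rtol=1e-8, atol=1e-8)

    def test_symmetry(self, rng):
        for _ in range(20):
            F = random_admissible_F(rng)
            sigma = cauchy_stress(PRINTED, DeformationState(F=F))
            np.testing.assert_allclose(sigma, sigma.T, atol=1e-10)

    def test_orthotropic_set_all_terms_engaged(self, rng):
        # full nine-parameter set keeps the FD consistency
        params = MaterialParamsHO(
            k=1000.0, a=0.5, b=5.0, a_ff=0.3, b_ff=4.0, a_ss=0.2, b_ss=3.0, a_fs=0.1, b_fs=2.0
        )
        for _ in range(20):
            F = random_admissible_F(rng)
            sigma = cauchy_stress(params, DeformationState(F=F))
            sigma_fd = fd_first_pk(params, F) @ F.T / np.linalg.det(F)
            np.testing.assert_allclose(sigma, 0.5 * (sigma_fd + sigma_fd.T), rtol=1e-4, atol=1e-6)


class TestShearRigs:
    def test_zero_gamma_gives_zero_stress(self):
        curve = shear_test(PRINTED, "FN", np.array([0.0]))
        assert curve.stress[0] == 0.0

    def test_fn_fs_identical_for_transversely_isotropic_set(self):
        # with a_ss = a_fs = 0 the energy is symmetric under s/n interchange
        gammas = np.linspace(0.0, 0.5, 21)
        fn = shear_test(PRINTED, "FN", gammas)
        fs = shear_test(PRINTED, "FS", gammas)
        np.testing.assert_array_equal(fn.stress, fs.stress)

    def test_ns_mode_isotropic_only(self):
        # NS engages neither the fiber nor (zero) sheet terms
        gammas = np.linspace(0.0, 0.4, 11)
        with_fiber = shear_test(PRINTED, "NS", gammas)
        without = shear_test(PRINTED.replace(a_ff=0.0), "NS", gammas)
        np.testing.assert_allclose(with_fiber.stress, without.stress, atol=1e-14)

    def test_fiber_modes_stiffer_than_cross_modes(self):
        gammas = np.array([0.4])
        fn = shear_test(PRINTED, "FN", gammas).stress[0]
        nf = shear_test(PRINTED, "NF", gammas).stress[0]
        assert fn > nf

    @pytest.mark.parametrize("mode", SHEAR_MODES)
    def test_all_modes_monotone(self, mode):
        gammas = np.linspace(0.0, 0.5, 26)
        curve = shear_test(PRINTED, mode, gammas)
        assert np.all(np.diff(curve.stress) > 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            shear_test(PRINTED, "XX", np.array([0.1]))


class TestExpLaw1D:
    def test_closed_form_value(self):
        law = ExpLaw1D(A=1.0, B=10.0)
        assert stress_1d(law, 0.1) == pytest.approx(np.e - 1.0, rel=1e-12)

    def test_zero_strain_zero_stress(self):
        assert stress_1d(ExpLaw1D(A=3.0, B=7.0), 0.0) == 0.0

    def test_chordae_variant_carries_no_compression(self):
        law = ExpLaw1D(A=2.0, B=30.0, tension_only=True)
        assert stress_1d(law, -0.05) == 0.0

    @given(
        A=st.floats(0.1, 50.0),
        B=st.floats(1.0, 60.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_convex(self, A, B):
        law = ExpLaw1D(A=A, B=B)
        eps = np.linspace(0.0, 0.5, 101)
        sigma = np.asarray(stress_1d(law, eps))
        assert np.all(np.diff(sigma) > 0)
        assert np.all(np.diff(sigma, 2) > -1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ExpLaw1D(A=-1.0, B=1.0)
        with pytest.raises(ValueError):
            ExpLaw1D(A=1.0, B=0.0)


class TestActiveTension:
    LAW = ActiveLaw(T_max=50.0, t_act=0.05, t_dur=0.4, length_dep=4.0)

    def test_zero_outside_window(self):
        assert active_tension(self.LAW, 0.0) == 0.0
        assert active_tension(self.LAW, 0.6) == 0.0

    def test_peak_at_window_midpoint(self):
        t_peak = self.LAW.t_act + self.LAW.t_dur / 2
        assert active_tension(self.LAW, t_peak, 1.0) == pytest.approx(50.0, rel=1e-12)

    def test_linear_in_t_max(self, rng):
        half = ActiveLaw(T_max=25.0, t_act=0.05, t_dur=0.4, length_dep=4.0)
        for _ in range(20):
            t = rng.uniform(0.0, 1.0)
            lam = rng.uniform(0.8, 1.3)
            assert active_tension(half, t, lam) == pytest.approx(
                0.5 * active_tension(self.LAW, t, lam), abs=1e-12
            )

    def test_length_dependence_clamped_nonnegative(self):
        t_peak = self.LAW.t_act + self.LAW.t_dur / 2
        assert active_tension(self.LAW, t_peak, 0.5) == 0.0


class TestStressStrainCurve:
    def test_round_trip_csv(self, tmp_path):
        gammas = np.linspace(0.0, 0.3, 7)
        curve = shear_test(PRINTED, "SN", gammas)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "mode,strain,stress_kPa"
        (back,) = StressStrainCurve.from_csv(path)
        assert back.mode == "SN"
        np.testing.assert_allclose(back.stress, curve.stress)

    def test_non_monotone_strain_rejected(self):
        with pytest.raises(ValueError):
            StressStrainCurve(mode="radial", strain=np.array([0.0, 0.2, 0.1]), stress=np.zeros(3))
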