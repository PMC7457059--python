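"""Constitutive-law unit tests: bone moduli, ligament bands, joint law, MR fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from sijstrain.materials import (
    JointLaw,
    LigamentLaw,
    MooneyRivlin3,
    derive_isotropic,
    fit_mooney_rivlin,
    mr_uniaxial_stress,
)

LAW = LigamentLaw()
JOINT = JointLaw()


class TestIsotropicElasticity:
    def test_derived_moduli_for_cortical_bone(self):
        # published to 5 significant figures: 1.4167e10 and 6.5385e9 Pa
        bone = derive_isotropic(1.7e10, 0.3)
        assert f"{bone.K:.4e}" == "1.4167e+10"
        assert f"{bone.G:.4e}" == "6.5385e+09"

    def test_zero_poisson_limit(self):
        bone = derive_isotropic(5.0e9, 0.0)
        assert bone.K == pytest.approx(5.0e9 / 3.0, rel=1e-14)
        assert bone.G == pytest.approx(5.0e9 / 2.0, rel=1e-14)

    @pytest.mark.parametrize("E,nu", [(-1.0, 0.3), (0.0, 0.3), (1e9, 0.5), (1e9, 0.7)])
    def test_invalid_parameters_rejected(self, E, nu):
        with pytest.raises(ValueError):
            derive_isotropic(E, nu)


class TestLigamentLaw:
    @pytest.mark.parametrize(
        "strain,expected",
        [
            (0.01, 39.0),
            (0.024999, 39.0),
            (0.025, 55.0),  # bands closed on the left
            (0.04, 55.0),
            (0.05, 103.0),
            (0.09, 103.0),
            (0.10, 100.0),
            (0.12, 100.0),
            (5.0, 100.0),
            (0.0, 0.0),
            (-0.05, 0.0),  # no stiffness in compression
        ],
    )
    def test_stiffness_band_lookup(self, strain, expected):
        assert LAW.stiffness(strain) == expected

    def test_force_zero_at_zero_elongation(self):
        assert LAW.force(0.0, 10.0) == 0.0
        assert LAW.force(-0.2, 10.0) == 0.0

    def test_force_first_band_closed_form(self):
        # constant 39 N/mm over an elongation of 0.025 * 10 mm
        assert LAW.force(0.025, 10.0) == pytest.approx(39.0 * 0.25, rel=1e-14)

    def test_force_matches_stiffness_quadrature(self):
        """Closed-form force equals numeric integration of the stiffness."""
        L0 = 17.3
        bps = [b * L0 for b in LAW.strain_breakpoints]
        for strain in np.linspace(1e-4, 0.3, 40):
            delta = strain * L0
            ref, _ = quad(
                lambda d: LAW.stiffness(d / L0), 0.0, delta,
                points=[b for b in bps if b < delta], limit=200,
            )
            assert LAW.force(strain, L0) == pytest.approx(ref, rel=1e-8)

    def test_force_continuous_at_band_boundaries(self):
        # a genuine step in force would be O(0.1 N); the probe-width bound
        # (k_left + k_right) * delta * L0 only allows the smooth part through
        L0, delta = 10.0, 1e-12
        for b in LAW.strain_breakpoints:
            jump = abs(LAW.force(b + delta, L0) - LAW.force(b - delta, L0))
            assert jump <= 2.0 * max(LAW.band_stiffness) * delta * L0

    def test_energy_zero_at_reference(self):
        assert LAW.energy(0.0, 12.0) == 0.0
        assert LAW.energy(-0.1, 12.0) == 0.0

    @pytest.mark.parametrize("strain", [0.01, 0.03, 0.07, 0.15, 0.025, 0.05])
    def test_energy_derivative_is_force(self, strain):
        L0, h = 10.0, 1e-7  # FD in strain: dE/d(delta) = (dE/ds)/L0
        dE = (LAW.energy(strain + h, L0) - LAW.energy(strain - h, L0)) / (2 * h)
        assert dE / L0 == pytest.approx(LAW.force(strain, L0), rel=1e-6)

    def test_energy_nondecreasing_in_strain(self):
        s = np.linspace(0.0, 0.3, 500)
        e = LAW.energy(s, 10.0)
        assert np.all(np.diff(e) >= 0)

    @given(st.floats(-0.5, 0.5), st.floats(0.5, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_force_nonnegative_and_energy_consistent(self, strain, L0):
        f = LAW.force(strain, L0)
        assert f >= 0.0
        assert LAW.energy(strain, L0) >= 0.0
        if strain <= 0:
            assert f == 0.0

    def test_invalid_rest_length(self):
        with pytest.raises(ValueError):
            LAW.force(0.1, 0.0)
        with pytest.raises(ValueError):
            LAW.energy(0.1, -3.0)

    def test_invalid_band_spec(self):
        with pytest.raises(ValueError):
            LigamentLaw(strain_breakpoints=(0.05, 0.025), band_stiffness=(1, 2, 3))
        with pytest.raises(ValueError):
            LigamentLaw(strain_breakpoints=(0.025,), band_stiffness=(1, 2, 3))


class TestJointLaw:
    def test_modulus_zero_at_zero_and_in_tension(self):
        assert JOINT.tangent_modulus(0.0) == 0.0
        assert JOINT.tangent_modulus(-0.1) == 0.0
        assert JOINT.stress(0.0) == 0.0
        assert JOINT.stress(-0.2) == 0.0

    def test_modulus_worked_value(self):
        assert JOINT.tangent_modulus(0.1) == pytest.approx(
            20.71 * 0.1 + 234 * 0.01, rel=1e-14
        )

    def test_stiffness_increases_with_compression(self):
        e = np.linspace(1e-4, 0.35, 100)
        m = JOINT.tangent_modulus(e)
        assert np.all(np.diff(m) > 0)
        assert JOINT.tangent_modulus(0.2) > JOINT.tangent_modulus(0.1)

    def test_stress_coefficients_from_integrating_modulus(self):
        """Quadrature of the tangent modulus recovers the stress polynomial."""
        assert JOINT.stress_coeff_quadratic == pytest.approx(10.355, abs=1e-12)
        assert JOINT.stress_coeff_cubic == pytest.approx(78.0, abs=1e-12)
        for eps in (0.05, 0.15, 0.30):
            ref, _ = quad(JOINT.tangent_modulus, 0.0, eps)
            assert JOINT.stress(eps) == pytest.approx(ref, rel=1e-10)

    def test_stress_derivative_is_modulus(self):
        h = 1e-7
        fd = (JOINT.stress(0.15 + h) - JOINT.stress(0.15 - h)) / (2 * h)
        assert fd == pytest.approx(JOINT.tangent_modulus(0.15), rel=1e-6)

    def test_energy_density_derivative_is_stress(self):
        h = 1e-7
        for eps in (0.05, 0.2):
            fd = (JOINT.energy_density(eps + h) - JOINT.energy_density(eps - h)) / (2 * h)
            assert fd == pytest.approx(JOINT.stress(eps), rel=1e-6)


class TestMooneyRivlin:
    def test_zero_stress_at_unit_stretch(self):
        p = MooneyRivlin3(c10=1.3, c01=-0.7, c11=2.0)
        assert mr_uniaxial_stress(p, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_neo_hookean_reduction(self):
        p = MooneyRivlin3(c10=0.8, c01=0.0, c11=0.0)
        for lam in (0.7, 0.9, 1.2, 1.6):
            expected = 2.0 * 0.8 * (lam - lam**-2)
            assert mr_uniaxial_stress(p, lam) == pytest.approx(expected, rel=1e-12)

    def test_nominal_stress_is_energy_derivative(self):
        p = MooneyRivlin3(c10=-1.8, c01=1.8, c11=2.0)
        h = 1e-5
        for lam in (0.75, 0.9, 1.1, 1.3):
            fd = (
                p.strain_energy_density(lam + h) - p.strain_energy_density(lam - h)
            ) / (2 * h)
            assert mr_uniaxial_stress(p, lam) == pytest.approx(fd, rel=1e-8)

    def test_invalid_stretch(self):
        p = MooneyRivlin3(c10=1.0, c01=0.0, c11=0.0)
        with pytest.raises(ValueError):
            mr_uniaxial_stress(p, 0.0)
        with pytest.raises(ValueError):
            mr_uniaxial_stress(p, -1.0)


class TestMooneyRivlinFit:
    def test_fit_residual_bound(self):
        mr = fit_mooney_rivlin(JOINT)
        assert mr.max_rel_error is not None
        assert mr.max_rel_error < 0.02

    def test_fit_deterministic(self):
        a = fit_mooney_rivlin(JOINT)
        b = fit_mooney_rivlin(JOINT)
        assert (a.c10, a.c01, a.c11) == (b.c10, b.c01, b.c11)

    def test_fitted_curve_within_recorded_error_everywhere(self):
        mr = fit_mooney_rivlin(JOINT, fit_range=(0.01, 0.30), n_samples=60)
        eps = np.linspace(0.01, 0.30, 60)
        pred = mr.stress(eps)
        ref = JOINT.stress(eps)
        rel = np.abs(pred - ref) / np.abs(ref)
        assert np.max(rel) <= mr.max_rel_error + 1e-12

    def test_fit_range_validation(self):
        with pytest.raises(ValueError):
            fit_mooney_rivlin(JOINT, fit_range=(0.0, 0.3))
        with pytest.raises(ValueError):
            fit_mooney_rivlin(JOINT, fit_range=(0.01, 0.5))
        with pytest.raises(ValueError):
            fit_mooney_rivlin(JOINT, n_samples=5)

    def test_compression_interface_consistent_with_joint_element_use(self):
        """MR stress/energy_density expose the same compressive-magnitude API."""
        mr = fit_mooney_rivlin(JOINT)
        assert mr.stress(-0.1) == 0.0
        assert mr.energy_density(-0.1) == 0.0
        h = 1e-6
        for eps in (0.05, 0.2):
            fd = (mr.energy_density(eps + h) - mr.energy_density(eps - h)) / (2 * h)
            assert fd == pytest.approx(mr.stress(eps), rel=1e-5)
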