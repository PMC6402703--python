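"""Laplace pressure, Love half-space deflection and the coupled equilibrium."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from beltsim import (
    BeltDesign,
    BodyElasticity,
    ContactModel,
    CurvatureField,
    PressureField,
    equilibrate,
    laplace_pressure,
    love_deflection,
    love_kernel,
    love_patch_deflection,
)
from beltsim.belt_placement import StrainField, TensionField
from beltsim.pressure_engine import MMHG_PER_PA, PA_PER_MMHG

from conftest import make_cylinder

R = 0.15
CENTER_Z = 0.2

# soft-body cases can trip the large-deflection diagnostic; the dedicated
# test asserts it explicitly with pytest.warns
pytestmark = pytest.mark.filterwarnings("ignore:maximum deflection")


def uniform_tension(shape, T1, T2=0.0):
    t1 = np.full(shape, float(T1))
    t2 = np.full(shape, float(T2))
    return TensionField(T1=t1, T2=t2,
                        strain=StrainField(eps1=t1 * 0, eps2=t2 * 0),
                        arc=np.zeros(shape))


class TestLaplacePressure:
    def test_cylinder_closed_form(self):
        shape = (36, 10)
        field = laplace_pressure(
            uniform_tension(shape, 2520.0),
            CurvatureField(gamma1=np.full(shape, 1.0 / R)),
        )
        assert np.allclose(field.p, 2520.0 / R, rtol=1e-12)  # 16.8 kPa

    def test_both_directions_add(self):
        shape = (36, 10)
        field = laplace_pressure(
            uniform_tension(shape, 1000.0, T2=500.0),
            CurvatureField(gamma1=np.full(shape, 4.0), gamma2=np.full(shape, 2.0)),
        )
        assert np.allclose(field.p, 1000.0 * 4.0 + 500.0 * 2.0)

    def test_concave_belt_direction_unloads_cell(self):
        shape = (36, 10)
        g1 = np.full(shape, 5.0)
        g1[3, :] = -5.0
        g2 = np.full(shape, 2.0)
        field = laplace_pressure(
            uniform_tension(shape, 1000.0, T2=500.0),
            CurvatureField(gamma1=g1, gamma2=g2),
        )
        assert np.all(field.p[3, :] == 0.0)  # lift-off beats the T2 term
        assert np.all(field.p[4, :] > 0.0)

    def test_concave_axial_contributes_nothing_negative(self):
        shape = (36, 10)
        field = laplace_pressure(
            uniform_tension(shape, 1000.0, T2=500.0),
            CurvatureField(gamma1=np.full(shape, 4.0), gamma2=np.full(shape, -2.0)),
        )
        assert np.allclose(field.p, 4000.0)

    def test_mask_zeroes_outside(self):
        shape = (36, 10)
        mask = np.zeros(shape, dtype=bool)
        mask[:, 3:6] = True
        field = laplace_pressure(
            uniform_tension(shape, 1000.0),
            CurvatureField(gamma1=np.full(shape, 4.0)),
            mask=mask,
        )
        assert np.all(field.p[~mask] == 0)
        assert np.all(field.p[mask] == 4000.0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="do not match"):
            laplace_pressure(uniform_tension((36, 10), 1.0),
                             CurvatureField(gamma1=np.ones((36, 9))))

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PressureField(p=np.array([[1.0, -0.1]]))

    def test_mmhg_conversion(self):
        f = PressureField(p=np.array([[1333.22]]))
        assert f.mmhg[0, 0] == pytest.approx(10.0, rel=1e-6)
        assert PA_PER_MMHG * MMHG_PER_PA == pytest.approx(1.0)


class TestLoveKernel:
    """Oracle: the kernel is the integral of the Boussinesq point-load
    Green's function 1/rho over the rectangle, computed by quadrature."""

    @pytest.mark.parametrize("x, y", [
        (0.013, 0.002), (0.0, 0.011), (-0.02, -0.017), (0.004, 0.0),
    ])
    def test_matches_boussinesq_quadrature(self, x, y):
        a, b = 0.005, 0.003
        oracle, err = dblquad(
            lambda eta, xi: 1.0 / np.hypot(x - xi, y - eta),
            -a, a, -b, b, epsabs=1e-13, epsrel=1e-11,
        )
        assert love_kernel(x, y, a, b) == pytest.approx(oracle, rel=1e-8)

    def test_centre_of_square_closed_form(self):
        # K(0, 0, a, a) = 8 a ln(1 + sqrt(2))
        a = 0.004
        assert love_kernel(0.0, 0.0, a, a) == pytest.approx(
            8 * a * np.log(1 + np.sqrt(2)), rel=1e-12)

    def test_far_field_approaches_point_load(self):
        a, b = 0.005, 0.003
        d = 20 * (2 * a)
        approx = 4 * a * b / d  # area / distance
        assert love_kernel(d, 0.0, a, b) == pytest.approx(approx, rel=0.01)

    def test_even_symmetry(self):
        a, b = 0.005, 0.003
        k = love_kernel(0.01, 0.007, a, b)
        assert love_kernel(-0.01, 0.007, a, b) == pytest.approx(k, rel=1e-12)
        assert love_kernel(0.01, -0.007, a, b) == pytest.approx(k, rel=1e-12)

    def test_patch_deflection_linear_in_pressure(self):
        el = BodyElasticity(youngs_modulus=20e3, poisson=0.45)
        u1 = love_patch_deflection(1000.0, el, 0.005, 0.003, 0.001, 0.0)
        u3 = love_patch_deflection(3000.0, el, 0.005, 0.003, 0.001, 0.0)
        assert u3 == pytest.approx(3 * u1, rel=1e-12)
        # compliance prefactor (1 - nu^2) / (pi E)
        assert u1 == pytest.approx(
            1000.0 * (1 - 0.45**2) / (np.pi * 20e3)
            * love_kernel(0.001, 0.0, 0.005, 0.003), rel=1e-12)


class TestLoveDeflectionFFT:
    def test_matches_direct_superposition(self):
        """FFT convolution equals an explicit O(n^2) sum on a small grid."""
        rng = np.random.default_rng(0)
        nt, nz = 24, 7
        arc, dz = 0.02, 0.01
        p = np.where(rng.random((nt, nz)) < 0.3, rng.uniform(500, 3000, (nt, nz)), 0.0)
        el = BodyElasticity(youngs_modulus=30e3, poisson=0.48)
        u_fft = love_deflection(p, el, arc, dz)
        u_direct = np.zeros((nt, nz))
        for i in range(nt):
            for j in range(nz):
                for k in range(nt):
                    for m in range(nz):
                        if p[k, m] == 0:
                            continue
                        di = min((i - k) % nt, (k - i) % nt)
                        u_direct[i, j] += p[k, m] * el.compliance * love_kernel(
                            di * arc, (j - m) * dz, arc / 2, dz / 2)
        assert np.abs(u_fft - u_direct).max() < 1e-12

    def test_linear_in_pressure(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 2000, (36, 10))
        el = BodyElasticity()
        u1 = love_deflection(p, el, 0.02, 0.01)
        u2 = love_deflection(2 * p, el, 0.02, 0.01)
        assert np.allclose(u2, 2 * u1, rtol=1e-12)

    def test_inverse_in_modulus(self):
        p = np.ones((36, 10)) * 1000
        u1 = love_deflection(p, BodyElasticity(youngs_modulus=15e3), 0.02, 0.01)
        u2 = love_deflection(p, BodyElasticity(youngs_modulus=30e3), 0.02, 0.01)
        assert np.allclose(u1, 2 * u2, rtol=1e-12)


class TestBodyElasticity:
    def test_validation(self):
        with pytest.raises(ValueError):
            BodyElasticity(youngs_modulus=0.0)
        with pytest.raises(ValueError):
            BodyElasticity(poisson=0.5)

    def test_compliance(self):
        el = BodyElasticity(youngs_modulus=10e3, poisson=0.0)
        assert el.compliance == pytest.approx(1.0 / (np.pi * 10e3))


class TestEquilibrate:
    def test_rigid_limit_recovers_undeformed_laplace(self, belt):
        """E -> inf: p = k_eq * 0.2 / R on the band, deflection ~ 0."""
        surf = make_cylinder(R, n_theta=120, n_z=40)
        state = equilibrate(
            surf, belt, ContactModel(locking="frictionless"),
            BodyElasticity(youngs_modulus=1e12), center_z=CENTER_Z,
        )
        assert state.converged
        T0 = belt.k_eq * 0.20
        band = state.placement.mask
        # polygon curvature differs from 1/R by the chord correction only
        assert np.abs(state.pressure.p[band] / (T0 / R) - 1).max() < 1e-2
        assert np.all(state.pressure.p[~band] == 0)
        assert np.abs(state.deflection.u_z).max() < 1e-7

    def test_soft_body_lowers_pressure(self, belt):
        surf = make_cylinder(R, n_theta=120, n_z=40)
        rigid = equilibrate(surf, belt, ContactModel(locking="frictionless"),
                            BodyElasticity(youngs_modulus=1e12), center_z=CENTER_Z)
        soft = equilibrate(surf, belt, ContactModel(locking="frictionless"),
                           BodyElasticity(youngs_modulus=80e3), center_z=CENTER_Z)
        assert soft.converged
        band = soft.placement.mask
        assert soft.pressure.p[band].mean() < 0.9 * rigid.pressure.p[band].mean()
        assert soft.deflection.u_z.max() > 1e-4

    def test_rigid_pressure_proportional_to_k_eq(self):
        surf = make_cylinder(R, n_theta=120, n_z=40)
        fields = []
        for k in (6e3, 12e3, 24e3):
            b = BeltDesign(name=f"k{k:.0f}", k_eq=k)
            st = equilibrate(surf, b, ContactModel(locking="frictionless"),
                             BodyElasticity(youngs_modulus=1e12), center_z=CENTER_Z)
            fields.append(st.pressure.p)
        assert np.allclose(fields[1], 2 * fields[0], rtol=1e-6)
        assert np.allclose(fields[2], 4 * fields[0], rtol=1e-6)

    def test_ramp_resolution_insensitive(self, belt):
        surf = make_cylinder(R, n_theta=120, n_z=40)
        el = BodyElasticity(youngs_modulus=80e3)
        means = []
        for n_steps in (5, 10):
            st = equilibrate(surf, belt, ContactModel(locking="frictionless"), el,
                             n_steps=n_steps, center_z=CENTER_Z)
            assert st.converged
            means.append(st.pressure.p[st.placement.mask].mean())
        assert abs(means[0] / means[1] - 1) < 0.01

    def test_residuals_recorded_and_below_tol(self, belt):
        surf = make_cylinder(R, n_theta=120, n_z=40)
        st = equilibrate(surf, belt, ContactModel(locking="frictionless"),
                         BodyElasticity(youngs_modulus=80e3), center_z=CENTER_Z,
                         tol=1e-3)
        assert st.residuals, "residual history must be recorded"
        assert st.residuals[-1] < 1e-3

    def test_large_deflection_warns(self, belt):
        surf = make_cylinder(R, n_theta=120, n_z=40)
        with pytest.warns(UserWarning, match="semi-infinite"):
            st = equilibrate(surf, belt, ContactModel(locking="frictionless"),
                             BodyElasticity(youngs_modulus=15e3), center_z=CENTER_Z)
        assert st.deflection.u_z.max() > 0.10 * R
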