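"""Parameter conversions, fiber kinematics, and the H-G-O energy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgofit.constitutive import (
    ElasticConstants,
    EnergyOverflowError,
    FiberParams,
    GroundParams,
    ParameterError,
    elastic_to_ground,
    ground_to_elastic,
    kinematics_uniaxial,
    nominal_stress_components,
    strain_energy,
)


class TestConversions:
    def test_posterior_row_from_young_modulus(self):
        # E = 0.46 MPa at nu = 0.49 reproduces the posterior table row
        gp = elastic_to_ground(ElasticConstants(0.46, 0.49))
        assert gp.C10 == pytest.approx(0.077, abs=5e-4)
        assert gp.D == pytest.approx(0.261, abs=5e-4)

    def test_anterior_modulus_converts_to_0638(self):
        # direct evaluation: E = 0.38 gives C10 = 0.0638 (3 s.f.), which is
        # *not* the 0.061 of the published anterior row — the two are
        # mutually inconsistent and the equations win here
        gp = elastic_to_ground(ElasticConstants(0.38, 0.49))
        assert gp.C10 == pytest.approx(0.0638, abs=5e-5)

    def test_doubling_E_doubles_C10_and_halves_D(self):
        a = elastic_to_ground(ElasticConstants(0.5, 0.49))
        b = elastic_to_ground(ElasticConstants(1.0, 0.49))
        assert b.C10 == pytest.approx(2 * a.C10, rel=1e-12)
        assert b.D == pytest.approx(a.D / 2, rel=1e-12)

    def test_nucleus_row_inverts_to_nu_049(self):
        ec = ground_to_elastic(GroundParams(0.168, 0.12))
        assert ec.E == pytest.approx(1.00, abs=5e-3)
        assert ec.nu == pytest.approx(0.490, abs=5e-4)

    def test_posterior_row_inverts_to_E_046(self):
        ec = ground_to_elastic(GroundParams(0.077, 0.261))
        assert ec.E == pytest.approx(0.46, abs=5e-3)

    @given(
        E=st.floats(0.01, 100.0),
        nu=st.floats(0.01, 0.499),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_is_identity(self, E, nu):
        ec = ground_to_elastic(elastic_to_ground(ElasticConstants(E, nu)))
        assert math.isclose(ec.E, E, rel_tol=1e-12)
        assert math.isclose(ec.nu, nu, rel_tol=1e-12)

    @pytest.mark.parametrize("E,nu", [(-1.0, 0.3), (0.0, 0.3), (1.0, 0.5),
                                      (1.0, 0.6), (1.0, 0.0)])
    def test_invalid_elastic_constants_rejected(self, E, nu):
        with pytest.raises(ParameterError):
            ElasticConstants(E, nu)


class TestKinematics:
    def test_identity_state(self):
        fp = FiberParams(1.0, 50.0, 0.01, 28.0)
        ks = kinematics_uniaxial(1.0, 1.0, 1.0, fp)
        assert ks.I1_bar == pytest.approx(3.0, abs=1e-14)
        assert ks.I4_bar_a == pytest.approx(1.0, abs=1e-14)
        assert ks.E_bar_a == pytest.approx(0.0, abs=1e-14)
        assert ks.J == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", [0.0, 15.0, 30.0, 45.0, 60.0, 90.0])
    def test_isotropic_dispersion_blends_out_theta(self, theta):
        # kappa = 1/3: E_bar = (1/3)(I1_bar - 3) regardless of fiber angle
        fp = FiberParams(1.0, 10.0, 1.0 / 3.0, theta)
        ks = kinematics_uniaxial(1.2, 0.95, 0.9, fp)
        assert ks.E_bar_a == pytest.approx((ks.I1_bar - 3.0) / 3.0, rel=1e-12)
        assert ks.E_bar_b == pytest.approx(ks.E_bar_a, rel=1e-12)

    def test_axial_fibers_see_axial_stretch(self):
        # theta = 90 deg puts the fibers along the load axis
        fp = FiberParams(1.0, 10.0, 0.0, 90.0)
        la = 1.1
        ks = kinematics_uniaxial(la, 1.0, 1.0, fp)
        assert ks.I4_bar_a == pytest.approx(la**2 * ks.J ** (-2.0 / 3.0), rel=1e-12)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ParameterError):
            kinematics_uniaxial(0.0, 1.0, 1.0)


class TestStrainEnergy:
    def test_zero_at_identity(self, posterior):
        ks = kinematics_uniaxial(1.0, 1.0, 1.0, posterior.fibers)
        assert strain_energy(posterior.ground, posterior.fibers, ks) == 0.0

    def test_slack_fibers_leave_ground_energy(self, posterior):
        # axial shortening with steep (near-axial) fibers: both fiber
        # strains negative, so the Macaulay bracket removes the fiber term
        fp = FiberParams(5.0, 100.0, 0.01, 75.0)
        ks = kinematics_uniaxial(0.9, 1.0, 1.0, fp)
        assert ks.E_bar_a < 0 and ks.E_bar_b < 0
        u_full = strain_energy(posterior.ground, fp, ks)
        u_ground = strain_energy(posterior.ground, None,
                                 kinematics_uniaxial(0.9, 1.0, 1.0))
        assert u_full == pytest.approx(u_ground, rel=1e-14)

    def test_matches_symbolic_evaluation(self, posterior):
        # independent symbolic oracle: evaluate the energy term by term
        # with sympy at the solved traction-free state at 10% extension
        sympy = pytest.importorskip("sympy")
        from hgofit.specimen import solve_uniaxial_state

        ks, _ = solve_uniaxial_state(posterior.ground, posterior.fibers, 1.1)
        l1, l2, l3 = sympy.symbols("l1 l2 l3", positive=True)
        C10, D, k1, k2, kap = [sympy.Rational(str(v)) for v in
                               (posterior.ground.C10, posterior.ground.D,
                                posterior.fibers.k1, posterior.fibers.k2,
                                posterior.fibers.kappa)]
        th = sympy.rad(sympy.Integer(28))
        J = l1 * l2 * l3
        I1b = J ** sympy.Rational(-2, 3) * (l1**2 + l2**2 + l3**2)
        I4b = J ** sympy.Rational(-2, 3) * (l1**2 * sympy.cos(th) ** 2
                                            + l3**2 * sympy.sin(th) ** 2)
        Eb = kap * (I1b - 3) + (1 - 3 * kap) * (I4b - 1)
        Ebp = sympy.Max(Eb, 0)
        U = (C10 * (I1b - 3) + (1 / D) * ((J**2 - 1) / 2 - sympy.log(J))
             + 2 * k1 / (2 * k2) * (sympy.exp(k2 * Ebp**2) - 1))
        expected = float(U.subs({l1: ks.lambda_t1, l2: ks.lambda_t2,
                                 l3: ks.lambda_axial}).evalf(30))
        got = strain_energy(posterior.ground, posterior.fibers, ks)
        assert got == pytest.approx(expected, rel=1e-10)

    @given(
        la=st.floats(0.75, 1.5),
        l1=st.floats(0.8, 1.2),
        l2=st.floats(0.8, 1.2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_positive_away_from_identity(self, la, l1, l2, posterior):
        ks = kinematics_uniaxial(la, l1, l2, posterior.fibers)
        u = strain_energy(posterior.ground, posterior.fibers, ks)
        if (abs(la - 1) + abs(l1 - 1) + abs(l2 - 1)) > 1e-6:
            assert u > 0.0
        else:
            assert u >= 0.0

    def test_zero_k1_coincides_with_neo_hookean(self, posterior):
        fp0 = FiberParams(0.0, 50.0, 0.01, 28.0)
        for la, l1, l2 in [(1.3, 0.9, 0.92), (0.8, 1.1, 1.05)]:
            u_f = strain_energy(posterior.ground, fp0,
                                kinematics_uniaxial(la, l1, l2, fp0))
            u_g = strain_energy(posterior.ground, None,
                                kinematics_uniaxial(la, l1, l2))
            assert u_f == pytest.approx(u_g, rel=1e-14)

    @pytest.mark.parametrize("theta", [0.0, 15.0, 30.0, 45.0, 60.0, 90.0])
    def test_isotropy_limit_energy_invariant_to_theta(self, posterior, theta):
        fp = FiberParams(2.0, 100.0, 1.0 / 3.0, theta)
        ks = kinematics_uniaxial(1.25, 0.9, 0.93, fp)
        fp0 = FiberParams(2.0, 100.0, 1.0 / 3.0, 0.0)
        ks0 = kinematics_uniaxial(1.25, 0.9, 0.93, fp0)
        u = strain_energy(posterior.ground, fp, ks)
        u0 = strain_energy(posterior.ground, fp0, ks0)
        assert u == pytest.approx(u0, rel=1e-12)

    def test_fiber_term_is_c1_across_activation(self):
        # the fiber stress (energy slope) must vanish continuously as the
        # fiber strain crosses zero from above
        fp = FiberParams(10.0, 500.0, 0.0, 90.0)
        gp = GroundParams(0.05, 0.3)
        theta = fp.theta_rad
        for eps in (1e-4, 1e-5, 1e-6):
            p_above = nominal_stress_components(
                gp.C10, gp.D, fp.k1, fp.k2, fp.kappa, theta,
                1.0, 1.0, (1.0 + eps))[2]
            p_below = nominal_stress_components(
                gp.C10, gp.D, 0.0, fp.k2, fp.kappa, theta,
                1.0, 1.0, (1.0 + eps))[2]
            # fiber contribution to the stress decays to zero with eps
            assert abs(float(p_above) - float(p_below)) < 200 * eps

    def test_overflow_raises(self):
        gp = GroundParams(0.05, 0.3)
        fp = FiberParams(10.0, 2000.0, 0.0, 90.0)
        ks = kinematics_uniaxial(2.5, 1.0, 1.0, fp)
        with pytest.raises(EnergyOverflowError):
            strain_energy(gp, fp, ks)
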