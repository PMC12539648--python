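"""Constituent energies, mixture stress and linearized stiffness."""
import math

import pytest
from hypothesis import given, strategies as st

from aortagnr.config import mmhg_to_kpa
from aortagnr.constitutive import (MixtureComposition, NonPhysicalStateError,
                                   fung_fiber_energy, mixture_cauchy_stress,
                                   mixture_response, mixture_stored_energy,
                                   neo_hookean_energy,
                                   small_on_large_stiffness)
from aortagnr.vessel_mechanics import LoadState, VesselState, laplace_stress


def state_at(params, lam_theta, lam_z=1.0, pressure=120.0, **comp_kw):
    comp = MixtureComposition(params=params, **comp_kw)
    return VesselState.from_stretch(comp, lam_theta, lam_z, LoadState(pressure))


class TestConstituentEnergies:
    def test_neo_hookean_undeformed_is_zero(self):
        assert neo_hookean_energy(3.0, 42.03) == 0.0

    def test_neo_hookean_at_elastin_deposition_stretch(self, params):
        # I1 from the elastin deposition stretch triple
        I1 = (params.G_theta_e ** 2 + params.G_z_e ** 2 + params.G_r_e ** 2)
        assert I1 == pytest.approx(8.11103, rel=1e-5)
        assert neo_hookean_energy(I1, 42.03) == pytest.approx(107.41, rel=1e-4)

    def test_neo_hookean_linear_in_modulus(self):
        assert neo_hookean_energy(5.0, 84.0) == 2 * neo_hookean_energy(5.0, 42.0)

    def test_neo_hookean_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            neo_hookean_energy(float("nan"), 42.0)

    def test_fung_unstretched_is_zero(self):
        assert fung_fiber_energy(1.0, 665.6, 2.14) == 0.0

    def test_fung_at_collagen_deposition_stretch(self):
        assert fung_fiber_energy(1.25 ** 2, 665.6, 2.14) == pytest.approx(
            75.28, rel=1e-3)

    def test_fung_at_muscle_deposition_stretch(self):
        assert fung_fiber_energy(1.19 ** 2, 1.26, 30.0) == pytest.approx(
            1.882, rel=1e-3)

    def test_fung_overflow_guard(self):
        with pytest.raises(NonPhysicalStateError):
            fung_fiber_energy(10.0, 665.6, 30.0)

    @given(x=st.floats(0.01, 0.45), c2=st.floats(0.5, 20.0))
    def test_fung_increases_with_stretch_deviation_and_exponent(self, x, c2):
        up = fung_fiber_energy(1.0 + 1.05 * x, 100.0, c2)
        assert up > fung_fiber_energy(1.0 + x, 100.0, c2) > 0
        assert fung_fiber_energy(1.0 + x, 100.0, 1.05 * c2) > \
            fung_fiber_energy(1.0 + x, 100.0, c2)

    @given(x=st.floats(0.01, 0.45))
    def test_fung_symmetric_in_stretch_deviation(self, x):
        assert fung_fiber_energy(1.0 + x, 50.0, 3.0) == pytest.approx(
            fung_fiber_energy(1.0 - x, 50.0, 3.0), rel=1e-12)


class TestMixtureEnergy:
    def test_rule_of_mixtures_additivity(self, params):
        """Mixture energy equals the mass-fraction-weighted constituent sum."""
        lam = 1.03
        W, *_ = mixture_response(MixtureComposition.baseline(params), lam, 1.0)
        I1 = ((lam * params.G_theta_e) ** 2 + params.G_z_e ** 2
              + (params.G_r_e / lam) ** 2)
        w_e = neo_hookean_energy(I1, params.ce_kPa)
        w_m = fung_fiber_energy((params.Gm * lam) ** 2, params.c1m_kPa,
                                params.c2m)
        a0 = math.radians(params.alpha0_deg)
        lam_d2 = (lam * math.sin(a0)) ** 2 + math.cos(a0) ** 2
        w_c = (params.beta_theta * fung_fiber_energy(
                   (params.Gc * lam) ** 2, params.c1c_kPa, params.c2c)
               + params.beta_z * fung_fiber_energy(
                   params.Gc ** 2, params.c1c_kPa, params.c2c)
               + params.beta_d * fung_fiber_energy(
                   params.Gc ** 2 * lam_d2, params.c1c_kPa, params.c2c))
        expected = (params.phi_e * w_e + params.phi_m * w_m
                    + params.phi_c * w_c)
        assert W == pytest.approx(expected, rel=1e-14)

    def test_zero_deformation_identity(self, params):
        """Near-unit deposition stretches and no load: no energy, no stress."""
        limp = params.with_(G_theta_e=1.0 + 1e-12, G_z_e=1.0 + 1e-12,
                            Gm=1.0 + 1e-12, Gc=1.0 + 1e-12)
        st_ = state_at(limp, 1.0, pressure=0.0)
        assert mixture_stored_energy(st_) == pytest.approx(0.0, abs=1e-15)
        stresses = mixture_cauchy_stress(st_, 0.0)
        assert all(abs(s) < 1e-7 for s in stresses)

    def test_baseline_systolic_energy(self, params):
        st_ = state_at(params, 1.0)
        assert mixture_stored_energy(st_) == pytest.approx(62.08, rel=1e-3)


class TestMixtureStress:
    def test_stress_energy_finite_difference_consistency(self, params):
        """sigma_tt - sigma_rr equals dW/dln(lam_theta) for isochoric
        biaxial perturbations (and the axial analogue)."""
        comp = MixtureComposition.baseline(params)
        for lam in (0.95, 1.0, 1.05):
            st_ = state_at(params, lam)
            s_t, s_z, s_r = mixture_cauchy_stress(st_, 0.0)
            eps = 1e-6
            for axis, sdev in (("theta", s_t - s_r), ("z", s_z - s_r)):
                def W(x):
                    lt = lam * math.exp(x) if axis == "theta" else lam
                    lz = math.exp(x) if axis == "z" else 1.0
                    return mixture_response(comp, lt, lz)[0]
                fd = (W(eps) - W(-eps)) / (2 * eps)
                assert sdev == pytest.approx(fd, rel=1e-5)

    def test_circumferential_fibre_loads_only_hoop_axis(self, params):
        """A 90-degree family contributes no axial extra stress."""
        only_theta = params.with_(beta_theta=1.0 - 2e-12, beta_z=1e-12,
                                  beta_d=1e-12, phi_e=1e-12, phi_m=1e-12,
                                  phi_c=1.0)
        _, s_t, s_z, s_r, _ = mixture_response(
            MixtureComposition.baseline(only_theta), 1.1, 1.0)
        assert s_t > 100.0
        assert abs(s_z) < 1e-6 * s_t
        assert abs(s_r) < 1e-6 * s_t

    def test_systolic_stress_close_to_laplace(self, params, targets):
        """Thin-ring equilibrium holds at the calibrated in-vivo state:
        the deviatoric hoop stress carries the transmural Laplace load."""
        st_ = state_at(params, 1.0)
        s_t, _, s_r = mixture_cauchy_stress(st_, 120.0,
                                            targets.perivascular_kPa)
        lap = laplace_stress(120.0, params.a0_mm, params.h0_mm) \
            - targets.perivascular_kPa * params.a0_mm / params.h0_mm
        assert s_t - s_r == pytest.approx(lap, rel=1e-10)

    def test_rejects_nonpositive_stretch(self, params):
        with pytest.raises(ValueError):
            mixture_response(MixtureComposition.baseline(params), -1.0, 1.0)


class TestStiffness:
    def test_against_finite_difference_oracle(self, params):
        """Analytic tangents match centred differences of the stress."""
        for lam, mc in ((0.96, 1.0), (1.0, 1.0), (1.1, 1.6)):
            comp = MixtureComposition(params=params, m_c=mc, m_m=mc,
                                      reset_stretch=(lam, 1.0) if mc > 1 else (1.0, 1.0))
            st_ = VesselState.from_stretch(comp, lam, 1.0, LoadState(80.0))
            c_t, c_z = small_on_large_stiffness(st_, 80.0)
            eps = 1e-6

            def sdev(lt, lz):
                _, s_t, s_z, s_r, _ = mixture_response(comp, lt, lz)
                return s_t - s_r, s_z - s_r

            fd_t = (sdev(lam * math.exp(eps), 1.0)[0]
                    - sdev(lam * math.exp(-eps), 1.0)[0]) / (2 * eps) / 1e3
            fd_z = (sdev(lam, math.exp(eps))[1]
                    - sdev(lam, math.exp(-eps))[1]) / (2 * eps) / 1e3
            assert c_t == pytest.approx(fd_t, rel=1e-4)
            assert c_z == pytest.approx(fd_z, rel=1e-4)

    def test_neo_hookean_closed_form(self, params):
        """Pure elastin mixture: tangent equals the closed-form value."""
        pure = params.with_(phi_e=1.0, phi_m=1e-12, phi_c=1e-12)
        lam = 1.05
        st_ = state_at(pure, lam, pressure=0.0)
        c_t, _ = small_on_large_stiffness(st_, 0.0)
        # condensed neo-Hookean tangent: 2 ce (lam_t^2 Gt^2 + lam_r^2 Gr^2)
        expect = 2.0 * pure.ce_kPa * (
            (lam * pure.G_theta_e) ** 2 + (pure.G_r_e / lam) ** 2) / 1e3
        assert c_t == pytest.approx(expect, rel=1e-6)

    def test_stiffening_with_pressure(self, params, targets):
        """Exponential fibres stiffen as the vessel is loaded further."""
        from aortagnr.vessel_mechanics import solve_elastic_state
        base = state_at(params, 1.0)
        cs = []
        for p in (80.0, 100.0, 120.0):
            st_ = solve_elastic_state(base, p,
                                      perivascular_kPa=targets.perivascular_kPa)
            cs.append(small_on_large_stiffness(st_, p)[0])
        assert cs[0] < cs[1] < cs[2]
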