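"""Unit and property tests of the three-site relaxation forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from naquad import constants as c
from naquad.relaxation_core import (DiffusionModel, ExperimentCondition,
                                    NucleusContext, QuadrupolarCoupling,
                                    SiteFractions, SiteMotion,
                                    aggregate_diffusion,
                                    aggregate_spectral_density, arrhenius_tau,
                                    effective_tau_with_exchange,
                                    lorentzian_spectral_density,
                                    micelle_surfactant_fraction,
                                    obstruction_factor, relaxation_rates,
                                    single_site_rates,
                                    stokes_einstein_diffusion,
                                    tau_from_surface_diffusion,
                                    total_spectral_density)

CTX = NucleusContext()
CHI = QuadrupolarCoupling.from_khz(117.0)

taus = st.floats(min_value=1e-12, max_value=1e-7)
fracs = st.floats(min_value=0.0, max_value=1.0)


class TestLorentzianSpectralDensity:
    def test_extreme_narrowing_limit_is_2tau_for_all_harmonics(self):
        tau = 1e-13  # w0 tau ~ 1e-4
        vals = [lorentzian_spectral_density(tau, n, CTX) for n in (0, 1, 2)]
        assert vals == pytest.approx([2 * tau] * 3, rel=1e-6)

    def test_zero_harmonic_is_field_independent(self):
        tau = 3e-9
        lo = NucleusContext(larmor_frequency=1e6)
        hi = NucleusContext(larmor_frequency=1e9)
        assert (lorentzian_spectral_density(tau, 0, lo)
                == lorentzian_spectral_density(tau, 0, hi) == 2 * tau)

    def test_frozen_value_at_033ns_n1_132mhz(self):
        # independent arbitrary-precision evaluation of the same formula
        assert lorentzian_spectral_density(0.33e-9, 1, CTX) == pytest.approx(
            6.14005318889e-10, rel=1e-10)

    @pytest.mark.parametrize("bad_tau", [0.0, -1e-9])
    def test_nonpositive_tau_rejected(self, bad_tau):
        with pytest.raises(ValueError):
            lorentzian_spectral_density(bad_tau, 1, CTX)

    @pytest.mark.parametrize("bad_n", [-1, 3, 5])
    def test_harmonic_outside_012_rejected(self, bad_n):
        with pytest.raises(ValueError):
            lorentzian_spectral_density(1e-9, bad_n, CTX)

    @given(t1=taus, t2=taus)
    def test_monotone_increasing_in_tau_at_zero_frequency(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert (lorentzian_spectral_density(lo, 0, CTX)
                <= lorentzian_spectral_density(hi, 0, CTX))

    @given(tau=taus, n=st.sampled_from([0, 1, 2]))
    def test_positive_and_finite(self, tau, n):
        j = lorentzian_spectral_density(tau, n, CTX)
        assert 0 < j < math.inf


def _motion(tau_m=0.32e-9, tau_c=0.29e-9, r1=22.1, r2=22.8, **kw):
    return SiteMotion(tau_m=tau_m, tau_c=tau_c, bulk_R1=r1, bulk_R2=r2, **kw)


class TestAggregateSpectralDensity:
    def test_degenerate_weights_select_single_site(self):
        motion = _motion()
        for n in (0, 1, 2):
            only_c = aggregate_spectral_density(
                SiteFractions(P_a=0.5, X_m=0.0), motion, n, CTX)
            only_m = aggregate_spectral_density(
                SiteFractions(P_a=0.5, X_m=1.0), motion, n, CTX)
            assert only_c == lorentzian_spectral_density(motion.tau_c, n, CTX)
            assert only_m == lorentzian_spectral_density(motion.tau_m, n, CTX)

    def test_two_thirds_weighting_matches_explicit_sum(self):
        # independently frozen two-term sum at tau_m=0.32, tau_c=0.29 ns, n=1
        got = aggregate_spectral_density(
            SiteFractions(P_a=1.0, X_m=2.0 / 3.0), _motion(), 1, CTX)
        assert got == pytest.approx(5.81351325564e-10, rel=1e-10)


class TestTotalSpectralDensityAndRates:
    def test_pure_bulk_reproduces_measured_reference_rates(self):
        motion = _motion(r1=22.1, r2=22.8)
        fr = SiteFractions(P_a=0.0, X_m=0.0)
        r1, r2 = relaxation_rates(fr, motion, CTX, CHI)
        assert r1 == pytest.approx(22.1, rel=1e-12)
        assert r2 == pytest.approx(22.8, rel=1e-12)

    def test_pure_aggregate_equals_aggregate_density(self):
        motion = _motion()
        fr = SiteFractions(P_a=1.0, X_m=0.5)
        for n in (0, 1, 2):
            assert (total_spectral_density(fr, motion, n, CTX, CHI)
                    == aggregate_spectral_density(fr, motion, n, CTX))

    def test_weighted_sum_at_700mm_composition(self):
        # hand-built oracle: explicit P_a-weighted sum of the two densities
        from naquad.relaxation_core import bulk_spectral_density
        motion = _motion(tau_m=0.32e-9, tau_c=0.29e-9)
        fr = SiteFractions(P_a=0.59, X_m=6.0 / 7.0)
        for n in (0, 1, 2):
            expected = (0.59 * aggregate_spectral_density(fr, motion, n, CTX)
                        + 0.41 * bulk_spectral_density(motion, n, CTX, CHI))
            assert total_spectral_density(fr, motion, n, CTX, CHI) == \
                pytest.approx(expected, rel=1e-14)

    def test_extreme_narrowing_rates_equal(self):
        r1, r2 = single_site_rates(1e-13, CTX, CHI)
        assert r2 == pytest.approx(r1, rel=1e-6)
        # and equal to the closed form 2 pi^2 chi^2 tau in the limit
        assert r1 == pytest.approx(2 * math.pi**2 * CHI.chi**2 * 1e-13,
                                   rel=1e-4)

    def test_chi_squared_scaling(self):
        motion = _motion()
        fr = SiteFractions(P_a=1.0, X_m=0.5)
        r1a, r2a = relaxation_rates(fr, motion, CTX, QuadrupolarCoupling(50e3))
        r1b, r2b = relaxation_rates(fr, motion, CTX, QuadrupolarCoupling(100e3))
        assert r1b == pytest.approx(4 * r1a, rel=1e-12)
        assert r2b == pytest.approx(4 * r2a, rel=1e-12)

    @given(tau_m=taus, tau_c=taus, xm=fracs, pa=fracs)
    def test_r2_never_below_r1(self, tau_m, tau_c, xm, pa):
        motion = _motion(tau_m=tau_m, tau_c=tau_c)
        r1, r2 = relaxation_rates(SiteFractions(P_a=pa, X_m=xm), motion,
                                  CTX, CHI)
        assert r2 >= r1 * (1 - 1e-12)

    @given(pa1=fracs, pa2=fracs, lam=fracs)
    def test_rates_affine_in_aggregate_fraction(self, pa1, pa2, lam):
        motion = _motion()

        def rates(pa):
            return np.array(relaxation_rates(
                SiteFractions(P_a=pa, X_m=0.4), motion, CTX, CHI))

        mixed = rates(lam * pa1 + (1 - lam) * pa2)
        combo = lam * rates(pa1) + (1 - lam) * rates(pa2)
        assert mixed == pytest.approx(combo, rel=1e-9)


class TestFractionBookkeeping:
    @pytest.mark.parametrize("conc,expected", [
        (50.0, 0.0), (300.0, 2.0 / 3.0), (700.0, 6.0 / 7.0)])
    def test_micelle_surfactant_fraction(self, conc, expected):
        cond = ExperimentCondition(concentration=conc, temperature=295.0)
        assert micelle_surfactant_fraction(cond) == pytest.approx(expected)

    def test_site_populations_sum_to_one(self):
        fr = SiteFractions(P_a=0.38, X_m=2.0 / 3.0)
        assert fr.micelle + fr.cluster + fr.P_b == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("pa,xm", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1),
                                       (0.5, 1.0001)])
    def test_invalid_fractions_rejected(self, pa, xm):
        with pytest.raises(ValueError):
            SiteFractions(P_a=pa, X_m=xm)


class TestCorrelationTimeLaws:
    def test_arrhenius_zero_barrier(self):
        assert arrhenius_tau(2e9, 0.0, 300.0) == pytest.approx(0.5e-9)

    @pytest.mark.parametrize("temp,expected_ns", [
        (275.0, 0.59), (283.0, 0.46), (295.0, 0.32)])
    def test_arrhenius_at_fitted_parameters(self, temp, expected_ns):
        tau = arrhenius_tau(1.6e13, 20.9e3, temp)
        assert tau * 1e9 == pytest.approx(expected_ns, abs=0.02)

    @pytest.mark.parametrize("r_ang,ds,expected_ns", [
        (27.0, 10.6e-10, 1.1), (14.5, 10.6e-10, 0.33)])
    def test_surface_diffusion_times(self, r_ang, ds, expected_ns):
        tau = tau_from_surface_diffusion(r_ang * 1e-10, ds)
        assert tau * 1e9 == pytest.approx(expected_ns, abs=0.05)

    def test_surface_diffusion_quadratic_in_radius(self):
        assert tau_from_surface_diffusion(2e-9, 1e-9) == pytest.approx(
            4 * tau_from_surface_diffusion(1e-9, 1e-9))

    def test_effective_tau_limits(self):
        assert effective_tau_with_exchange(0.33e-9, math.inf) == 0.33e-9
        assert effective_tau_with_exchange(2e-9, 2e-9) == pytest.approx(1e-9)

    def test_effective_tau_slow_exchange_barely_matters(self):
        tau = effective_tau_with_exchange(0.33e-9, 10e-9)
        assert tau == pytest.approx(3.19457889642e-10, rel=1e-10)
        assert abs(tau / 0.33e-9 - 1) < 0.04  # < 4% shift


class TestDiffusion:
    MODEL = DiffusionModel(D_b=10.7e-10, viscosity=1.18e-3)

    def test_pure_bulk_gives_measured_diffusion(self):
        cond = ExperimentCondition(concentration=50.0, temperature=295.0)
        _, d_eff = aggregate_diffusion(self.MODEL, cond,
                                       SiteFractions(P_a=0.0, X_m=0.0))
        assert d_eff == pytest.approx(10.7e-10, rel=1e-12)

    def test_obstruction_factor_is_unity_at_zero_volume_fraction(self):
        assert obstruction_factor(0.0) == 1.0
        with pytest.raises(ValueError):
            obstruction_factor(1.0)

    def test_stokes_einstein_micelle_at_295K(self):
        # frozen hand evaluation of kT/(6 pi eta R)
        got = stokes_einstein_diffusion(295.0, 1.18e-3, 27.0e-10)
        assert got == pytest.approx(6.78200966126e-11, rel=1e-10)

    def test_volume_fraction_caps_at_unity(self):
        model = DiffusionModel(D_b=1e-9, viscosity=1e-3,
                               partial_molar_volume=2e-3)
        cond = ExperimentCondition(concentration=700.0, temperature=295.0)
        with pytest.raises(ValueError):
            model.volume_fraction(cond)

    @given(pa=fracs, xm=fracs)
    def test_effective_diffusion_bounded_by_site_coefficients(self, pa, xm):
        cond = ExperimentCondition(concentration=700.0, temperature=295.0)
        fr = SiteFractions(P_a=pa, X_m=xm)
        d_a, d_eff = aggregate_diffusion(self.MODEL, cond, fr)
        obst = obstruction_factor(self.MODEL.volume_fraction(cond))
        d_m = stokes_einstein_diffusion(295.0, 1.18e-3, 27e-10) * obst
        d_c = stokes_einstein_diffusion(295.0, 1.18e-3, 6.4e-10) * obst
        assert min(d_m, d_c) - 1e-18 <= d_a <= max(d_m, d_c) + 1e-18
        lo = min(d_m, d_c, self.MODEL.D_b) - 1e-18
        hi = max(d_m, d_c, self.MODEL.D_b) + 1e-18
        assert lo <= d_eff <= hi


def test_nucleus_angular_frequency_consistent():
    ctx = NucleusContext(larmor_frequency=132e6)
    assert ctx.angular_frequency == pytest.approx(2 * math.pi * 132e6)
    with pytest.raises(ValueError):
        NucleusContext(larmor_frequency=-1.0)
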