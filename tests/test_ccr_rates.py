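"""CCR rate expressions, the J(0)-isolating combination and the Q ratio."""

import math

import numpy as np
import pytest

from ccrq.ccr_rates import (
    PhysicalConstants,
    RateSet,
    cca_pair,
    gamma_xy_C,
    gamma_xy_N,
    gamma_z_C,
    gamma_z_N,
    k_prefactor,
    nh_pair,
    q_ratio,
    q_record,
    rate_sets,
)
from ccrq.geometry import p2
from ccrq.spectral_density import DiffusionModel, MotionModel, iso_ratio_limit


class TestPrefactor:
    def test_channel_ratio_from_constant_arithmetic(self, consts):
        """k_C'/C'Ca / k_N/NH must equal gc^3 r_NH^3 / (gn^2 gh r_C'Ca^3),
        evaluated here independently from the raw constants."""
        expected = (
            consts.gamma_c**3 * 1.04**3
            / (consts.gamma_n**2 * consts.gamma_h * 1.53**3)
        )
        ratio = k_prefactor(cca_pair(consts), consts) / k_prefactor(
            nh_pair(consts), consts
        )
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(0.486, abs=5e-4)

    def test_inverse_cube_distance_scaling(self, consts):
        k1 = k_prefactor(nh_pair(consts, 1.04), consts)
        k2 = k_prefactor(nh_pair(consts, 2.08), consts)
        assert k2 == pytest.approx(k1 / 8.0, rel=1e-12)

    def test_nitrogen_sign_irrelevant(self, consts):
        flipped = PhysicalConstants(gamma_n=-consts.gamma_n)
        assert k_prefactor(nh_pair(flipped), flipped) == pytest.approx(
            k_prefactor(nh_pair(consts), consts), rel=1e-12
        )


class TestNitrogenRates:
    def test_zero_spectrum_gives_zero(self, consts):
        pair = nh_pair(consts)
        assert gamma_xy_N(0.0, 0.0, pair, consts) == 0.0
        assert gamma_z_N(0.0, pair, consts) == 0.0

    def test_white_spectrum_coefficients(self, consts):
        """Flat J = tau: Gxy = 7 k dN tau, Gz = 6 k dN tau."""
        pair = nh_pair(consts)
        tau = 1e-9
        k_dn = k_prefactor(pair, consts) * 170.0
        assert gamma_xy_N(tau, tau, pair, consts) == pytest.approx(7 * k_dn * tau)
        assert gamma_z_N(tau, pair, consts) == pytest.approx(6 * k_dn * tau)

    def test_j0_combination_is_4k_dn_j0(self, consts):
        pair = nh_pair(consts)
        j0, jw = 0.8e-9, 0.3e-9
        rs = RateSet("N/NH", gamma_xy_N(j0, jw, pair, consts),
                     gamma_z_N(jw, pair, consts))
        assert rs.j0_combination == pytest.approx(
            4.0 * k_prefactor(pair, consts) * 170.0 * j0, rel=1e-12
        )

    def test_rigid_isotropic_closed_form(self, plane, consts):
        """Full pipeline, S^2 = 1, isotropic 1 ns: Gxy equals
        k dN P2(cos 20) [4 tau + 3 tau / (1 + (wN tau)^2)]."""
        d = DiffusionModel.from_tau_eff(1e-9, 1.0)
        n_rates, _ = rate_sets(plane, d, MotionModel(s2=1.0), consts)
        tau = 1e-9
        proj = p2(math.cos(math.radians(20.0)))
        k_dn = k_prefactor(nh_pair(consts), consts) * 170.0
        expected = k_dn * proj * (
            4 * tau + 3 * tau / (1 + (consts.omega_n * tau) ** 2)
        )
        assert n_rates.gamma_xy == pytest.approx(expected, rel=1e-9)

    def test_negative_j0_warns(self, consts):
        with pytest.warns(RuntimeWarning, match="negative"):
            gamma_xy_N(-1e-9, 0.0, nh_pair(consts), consts)


class TestCarbonylRates:
    def test_zero_and_symmetric_csa_limits(self, consts):
        pair = cca_pair(consts)
        assert gamma_xy_C(0, 0, 0, 0, pair, consts) == 0.0
        assert gamma_z_C(0, 0, pair, consts) == 0.0
        s = 150.0
        assert gamma_xy_C(1e-9, 1e-9, 1e-9, 1e-9, pair, consts,
                          sigma_xx=s, sigma_yy=s, sigma_zz=s) == 0.0

    def test_j0_combination_matches_weighted_j0_sum(self, consts):
        """Gxy - 0.5 Gz = 4k [(sxx-szz) Jxx(0) + (syy-szz) Jyy(0)] exactly."""
        pair = cca_pair(consts)
        jxx0, jxxw, jyy0, jyyw = 0.9e-9, 0.35e-9, -0.2e-9, -0.1e-9
        rs = RateSet(
            "C/CCA",
            gamma_xy_C(jxx0, jxxw, jyy0, jyyw, pair, consts),
            gamma_z_C(jxxw, jyyw, pair, consts),
        )
        k = k_prefactor(pair, consts)
        expected = 4.0 * k * ((249.4 - 87.9) * jxx0 + (191.1 - 87.9) * jyy0)
        assert rs.j0_combination == pytest.approx(expected, rel=1e-12)

    def test_symmetric_csa_reduces_to_single_delta(self, consts):
        pair = cca_pair(consts)
        g = gamma_z_C(0.4e-9, 0.1e-9, pair, consts,
                      sigma_xx=200.0, sigma_yy=200.0, sigma_zz=90.0)
        k = k_prefactor(pair, consts)
        assert g == pytest.approx(k * 110.0 * 6.0 * (0.4e-9 + 0.1e-9), rel=1e-12)


class TestJZeroIsolation:
    def test_combination_independent_of_larmor_frequency(self, plane):
        """Scaling B0 (hence all Larmor frequencies) by 10 changes Gxy and Gz
        individually but not (Gxy - 0.5 Gz) / B0."""
        d = DiffusionModel.from_tau_eff(1.5e-9, 2.0, beta=25.0)
        m = MotionModel(s2=0.8, tau_int=200e-12)
        combos = []
        for b0 in (18.8, 188.0):
            c = PhysicalConstants(b0=b0)
            n_rates, c_rates = rate_sets(plane, d, m, c)
            combos.append(
                (n_rates.j0_combination / b0, c_rates.j0_combination / b0)
            )
        assert combos[0][0] == pytest.approx(combos[1][0], rel=1e-12)
        assert combos[0][1] == pytest.approx(combos[1][1], rel=1e-12)


class TestQRatio:
    def test_identical_rate_sets_give_unity(self):
        rs = RateSet("N/NH", 2.0, 0.6)
        assert q_ratio(rs, rs) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            q_ratio(RateSet("C/CCA", 1.0, 0.5), RateSet("N/NH", 0.5, 1.0))

    def test_isotropic_baseline_against_hand_evaluation(self, plane, consts):
        """Isotropic Q must equal the closed form
        k_ratio [(sxx-szz) P2(cos 29) + (syy-szz) P2(cos 61)] / (dN P2(cos 20)),
        which evaluates to 0.31."""
        d = DiffusionModel.from_tau_eff(1e-9, 1.0, beta=48.0)
        rec = q_record(plane, d, MotionModel(s2=0.4, tau_int=300e-12), consts)
        k_ratio = k_prefactor(cca_pair(consts), consts) / k_prefactor(
            nh_pair(consts), consts
        )
        cosd = lambda a: math.cos(math.radians(a))
        closed = k_ratio * (
            (249.4 - 87.9) * p2(cosd(29.0)) + (191.1 - 87.9) * p2(cosd(61.0))
        ) / (170.0 * p2(cosd(20.0)))
        assert rec.q == pytest.approx(closed, rel=1e-9)
        assert rec.q == pytest.approx(0.31, abs=0.01)

    def test_field_cancellation(self, plane):
        d = DiffusionModel.from_tau_eff(1e-9, 2.5, beta=60.0)
        m = MotionModel(s2=0.9, tau_int=100e-12)
        qs = []
        for b0 in (14.1, 18.8):
            rec = q_record(plane, d, m, PhysicalConstants(b0=b0))
            qs.append(rec.q)
        assert qs[0] == pytest.approx(qs[1], rel=1e-12)

    def test_size_rescaling_invariance_at_s2_one(self, plane, consts):
        """Rigid-limit Q depends on the anisotropy, not on the overall size
        of the diffusion tensor."""
        m = MotionModel(s2=1.0)
        qs = []
        for scale in (1.0, 3.7):
            d = DiffusionModel(2.5e8 * scale, 1e8 * scale, beta=80.0)
            qs.append(q_record(plane, d, m, consts).q)
        assert qs[0] == pytest.approx(qs[1], rel=1e-12)

    @pytest.mark.parametrize("s2", [0.0, 0.3, 0.7, 1.0])
    @pytest.mark.parametrize("tau_eff", [1e-9, 2.5e-9])
    @pytest.mark.parametrize("tau_int", [100e-12, 500e-12])
    def test_anisotropy_one_equals_iso_closed_form(
        self, plane, consts, s2, tau_eff, tau_int
    ):
        """At D_par/D_perp = 1 the full pipeline collapses onto the geometric
        P2-ratio closed form for every point of the dynamics grid."""
        d = DiffusionModel.from_tau_eff(tau_eff, 1.0, beta=15.0)
        rec = q_record(plane, d, MotionModel(s2=s2, tau_int=tau_int), consts)
        k_ratio = k_prefactor(cca_pair(consts), consts) / k_prefactor(
            nh_pair(consts), consts
        )
        num = (249.4 - 87.9) * iso_ratio_limit(0.0, -29.0, 57.0, 37.0) + (
            191.1 - 87.9
        ) * iso_ratio_limit(0.0, 61.0, 57.0, 37.0)
        closed = k_ratio * num / 170.0
        assert abs(rec.q - closed) < 1e-9 * abs(closed)
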