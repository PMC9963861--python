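"""Spectral-density kernels against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdfit.constants import CONSTANTS
from nmrdfit.spectral import (
    _FFHS_NORM,
    FFHSParams,
    QREParams,
    SurfaceDiffusionParams,
    cdd_hn_from_distance,
    d_from_tau,
    j2d,
    j2d_long_residence,
    j3d_ffhs,
    lorentzian_r1,
    qre_peak_frequencies,
    r1_qre_hn,
    r1_translational_3d,
    tau_from_d,
)

# frozen before the main build: trapezoid-with-Richardson value of the
# reduced FFHS integral at zero frequency (scipy quad agrees to 1e-10)
FFHS_REDUCED_AT_ZERO = 0.0258567296591752
# frozen hand computation of (2/3)(mu0/4pi gH gN hbar / r^3)^2 at r = 1 A
CDD_HN_AT_1A = 1.9842411149e9


def ffhs_brute_force(omega: float, tau: float, umax: float = 400.0,
                     n: int = 400_001) -> float:
    """Independent trapezoid oracle with one Richardson refinement step."""
    def integral(npts):
        u = np.linspace(1e-12, umax, npts)
        f = u**4 / (81 + 9 * u**2 - 2 * u**4 + u**6) \
            / (u**4 + (omega * tau) ** 2)
        return np.trapezoid(f, u)

    coarse = integral((n - 1) // 2 + 1)
    fine = integral(n)
    return _FFHS_NORM * tau * (fine + (fine - coarse) / 3.0)


class TestLorentzian:
    def test_zero_frequency_plateau_is_5_C_tau(self):
        assert lorentzian_r1(1e6, 1e-7, 0.0) == pytest.approx(0.5, rel=1e-12)
        # 20%wt 268 K intermediate component
        assert lorentzian_r1(7.84e6, 1.97e-7, 0.0) == pytest.approx(
            7.7224, rel=1e-12)

    def test_high_frequency_limit_vanishes(self):
        # ~ 2 C / (omega^2 tau) decay
        assert lorentzian_r1(1e8, 1e-6, 1e12) < 1e-9
        assert lorentzian_r1(1e8, 1e-6, 1e15) < 1e-15

    @given(st.floats(1e4, 1e10), st.floats(1e-12, 1e-4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_even_and_non_increasing(self, C, tau):
        omega = np.geomspace(1e2, 1e10, 50)
        r = lorentzian_r1(C, tau, omega)
        assert np.all(np.diff(r) <= 1e-12 * r[:-1] + 1e-300)
        assert np.allclose(lorentzian_r1(C, tau, -omega), r)
        assert np.all(r >= 0)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            lorentzian_r1(1e6, 0.0, 1.0)


class TestFFHS:
    def test_agrees_with_brute_force_oracle(self, rng):
        """Adaptive-quadrature/spline path vs independent trapezoid oracle
        at 20 random (omega, tau) points, 1e-6 relative."""
        for _ in range(20):
            tau = 10 ** rng.uniform(-10, -6)
            nu = 10 ** rng.uniform(3.5, 7.5)
            omega = 2 * math.pi * nu
            ours = j3d_ffhs(np.array([omega]), tau)[0]
            oracle = ffhs_brute_force(omega, tau)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_zero_frequency_value_pinned(self):
        assert j3d_ffhs(np.array([0.0]), 1.0)[0] == pytest.approx(
            _FFHS_NORM * FFHS_REDUCED_AT_ZERO, rel=1e-7)

    def test_high_frequency_limit_vanishes(self):
        assert j3d_ffhs(np.array([1e12]), 1.0)[0] < 1e-12

    def test_monotone_non_increasing(self):
        omega = np.geomspace(1e0, 1e10, 200)
        j = j3d_ffhs(omega, 1e-8)
        assert np.all(np.diff(j) <= 0)
        assert np.all(j > 0)

    def test_translational_rate_linear_in_density(self, rng):
        omega = 2 * math.pi * np.geomspace(1e4, 2e7, 10)
        p1 = FFHSParams(N_H=1.52e27, d=2.7e-10, tau_trans=3.5e-8)
        p2 = FFHSParams(N_H=2 * 1.52e27, d=2.7e-10, tau_trans=3.5e-8)
        p0 = FFHSParams(N_H=0.0, d=2.7e-10, tau_trans=3.5e-8)
        r1 = r1_translational_3d(p1, omega)
        assert np.allclose(r1_translational_3d(p2, omega), 2 * r1, rtol=1e-12)
        assert np.all(r1_translational_3d(p0, omega) == 0)

    def test_translational_rate_pinned_by_oracle(self):
        """20%wt 268 K 3D-diffusion parameter set at 10 kHz."""
        p = FFHSParams(N_H=1.52e27, d=2.7e-10, tau_trans=3.5e-8)
        omega = 2 * math.pi * 1e4
        pref = 1.5 * (CONSTANTS.mu0 / (4 * math.pi) * CONSTANTS.gamma_H**2
                      * CONSTANTS.hbar) ** 2 * p.N_H / p.d**3
        oracle = pref * (ffhs_brute_force(omega, p.tau_trans)
                         + 4 * ffhs_brute_force(2 * omega, p.tau_trans))
        ours = r1_translational_3d(p, np.array([omega]))[0]
        assert ours == pytest.approx(oracle, rel=1e-6)


class TestSurface2D:
    def test_zero_frequency_closed_form(self):
        # 2 tau ln(tau_res/tau)
        val = j2d(np.array([0.0]), 1e-8, 1e-7)[0]
        assert val == pytest.approx(2e-8 * math.log(10.0), rel=1e-12)
        assert val == pytest.approx(4.6052e-8, rel=1e-4)

    def test_long_residence_diverges_at_zero(self):
        with pytest.raises(ValueError):
            j2d_long_residence(np.array([0.0]), 1e-8)

    def test_high_frequency_limit_vanishes(self):
        assert j2d_long_residence(np.array([1e14]), 1e-8)[0] < 1e-18

    def test_low_frequency_log_slope(self):
        """Long-residence 2D density is linear in ln(omega) with slope
        -2 tau at omega*tau << 1 (regression oracle)."""
        tau = 1e-8
        omega = np.geomspace(1e2, 1e4, 40)  # omega*tau in [1e-6, 1e-4]
        j = j2d_long_residence(omega, tau)
        slope = np.polyfit(np.log(omega), j, 1)[0]
        assert slope == pytest.approx(-2 * tau, rel=1e-6)

    def test_converges_to_long_residence_limit(self):
        """Finite-residence density approaches the long-residence limit
        uniformly on the acquisition grid as tau_res/tau -> inf."""
        tau = 1e-8
        omega = 2 * math.pi * np.geomspace(1e4, 2e7, 60)
        lim = j2d_long_residence(omega, tau)
        dev = {ratio: np.max(np.abs(j2d(omega, tau, ratio * tau) - lim)
                             / lim)
               for ratio in (1e3, 1e6)}
        assert dev[1e6] < 1e-5
        assert dev[1e6] < dev[1e3] / 1e3  # ~1/ratio^2 convergence

    def test_residence_must_exceed_correlation_time(self):
        with pytest.raises(ValueError):
            SurfaceDiffusionParams(C_trans=1e7, tau_trans=1e-7, tau_res=1e-8)


class TestQRE:
    def test_peak_frequencies_printed_values(self):
        nu_m, nu_p, nu_0 = qre_peak_frequencies(3.36e6, 0.42)
        assert nu_m == pytest.approx(2.8896e6, rel=1e-12)
        assert nu_p == pytest.approx(3.8304e6, rel=1e-12)
        assert nu_0 == pytest.approx(0.9408e6, rel=1e-12)

    def test_peak_frequency_algebra(self):
        assert qre_peak_frequencies(1.0, 0.0) == (1.0, 1.0, 0.0)
        nu_m, nu_p, nu_0 = qre_peak_frequencies(3.0, 0.9)
        assert nu_0 == pytest.approx(2 * 3.0 * 0.9 / 3, rel=1e-12)
        assert nu_m < nu_p

    @given(st.floats(0, 90), st.floats(0, 90))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_angular_weights_sum_to_two(self, theta, phi):
        th, ph = math.radians(theta), math.radians(phi)
        w = ((1 / 3 + math.sin(th) ** 2 * math.cos(ph) ** 2)
             + (1 / 3 + math.sin(th) ** 2 * math.sin(ph) ** 2)
             + (1 / 3 + math.cos(th) ** 2))
        assert w == pytest.approx(2.0, abs=1e-12)

    def test_zero_coupling_gives_zero(self):
        p = QREParams(C_DD_HN=0.0, a_Q=3.36e6, eta=0.42, tau_Q=1e-6,
                      theta=55.4, phi=53.0)
        omega = 2 * math.pi * np.geomspace(1e4, 2e7, 30)
        assert np.all(r1_qre_hn(p, omega) == 0)

    def test_peaks_at_quadrupole_transition_frequencies(self):
        """Local maxima of the synthesized pattern within one linewidth of
        nu-, nu+ and nu0 (slow-motion regime, omega0 tauQ >> 1)."""
        p = QREParams(C_DD_HN=2.27e7, a_Q=3.36e6, eta=0.42, tau_Q=1.03e-6,
                      theta=55.4, phi=53.0)
        nu = np.linspace(2e5, 6e6, 30000)
        r = r1_qre_hn(p, 2 * math.pi * nu)
        assert np.all(r > 0)
        maxima = nu[1:-1][(r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])]
        linewidth = 1.0 / (2 * math.pi * p.tau_Q)
        for target in (0.9408e6, 2.8896e6, 3.8304e6):
            assert np.min(np.abs(maxima - target)) < linewidth

    def test_eta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            QREParams(C_DD_HN=1e7, a_Q=3.36e6, eta=1.2, tau_Q=1e-6,
                      theta=10, phi=10)


class TestConversions:
    @pytest.mark.parametrize("tau, expected", [
        (5.17e-8, 7.05e-13),   # residence-model 20%wt 268 K
        (7.26e-10, 5.02e-11),  # long-residence 20%wt 268 K
        (7.14e-9, 5.11e-12),   # long-residence 40%wt 266 K
        (1.83e-7, 1.99e-13),   # residence-model 40%wt 266 K
    ])
    def test_printed_diffusion_coefficients(self, tau, expected):
        assert d_from_tau(tau, 2.7e-10) == pytest.approx(expected, rel=5e-3)

    @given(st.floats(1e-10, 1e-6), st.floats(1e-10, 1e-9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip_identity(self, tau, d):
        assert tau_from_d(d_from_tau(tau, d), d) == pytest.approx(
            tau, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            d_from_tau(-1e-8, 2.7e-10)
        with pytest.raises(ValueError):
            tau_from_d(1e-12, 0.0)


class TestDipolarConstant:
    def test_value_pinned_by_hand_computation(self):
        assert cdd_hn_from_distance(1e-10) == pytest.approx(
            CDD_HN_AT_1A, rel=1e-9)

    def test_inverse_sixth_power(self):
        assert cdd_hn_from_distance(2e-10) == pytest.approx(
            cdd_hn_from_distance(1e-10) / 64.0, rel=1e-12)
        assert cdd_hn_from_distance(1e-3) < 1e-30

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            cdd_hn_from_distance(0.0)
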