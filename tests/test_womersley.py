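"""Womersley closed forms: centerline-to-flow conversion and profiles.

The independent oracle throughout is numerical quadrature of the analytic
radial (tube) or transverse (channel) velocity profile.
"""

import numpy as np
import pytest
from scipy.special import jv

from graftflow.errors import ValidationError
from graftflow.waveforms import FlowWaveform, VelocityWaveform, fourier_decompose
from graftflow.womersley import (
    FluidProperties,
    channel_flow_from_centerline,
    channel_flow_to_centerline_ratio,
    channel_profile,
    flow_from_centerline,
    inlet_profile,
    tube_flow_to_centerline_ratio,
    viscosity_from_hematocrit,
    womersley_number,
)

FLUID = FluidProperties(rho=1060.0, mu=1060.0 * 3.3e-6)  # nu = 3.3e-6 m^2/s


def tube_ratio_quadrature(alpha, R, n=200_001):
    """Oracle: 2 pi int u(r) r dr / u_c for the analytic tube profile."""
    L = alpha * np.exp(0.75j * np.pi)
    r = np.linspace(0.0, R, n)
    prof = 1.0 - jv(0, L * r / R) / jv(0, L)
    uc = 1.0 - 1.0 / jv(0, L)
    return 2.0 * np.pi * np.trapezoid(prof * r, r) / uc


def channel_ratio_quadrature(alpha, a, n=200_001):
    lam = alpha * np.exp(0.25j * np.pi)
    y = np.linspace(-a, a, n)
    prof = 1.0 - np.cosh(lam * y / a) / np.cosh(lam)
    uc = 1.0 - 1.0 / np.cosh(lam)
    return np.trapezoid(prof, y) / uc


class TestWomersleyNumber:
    def test_steady_limit_is_zero(self):
        assert womersley_number(3e-3, 0.0, 3.3e-6) == 0.0

    def test_reference_value(self):
        # alpha^2 = R^2 omega / nu (dimensional-analysis oracle)
        R, omega, nu = 3e-3, 2 * np.pi, 3.3e-6
        alpha = womersley_number(R, omega, nu)
        assert alpha == pytest.approx(np.sqrt(R * R * omega / nu), rel=1e-12)
        assert alpha == pytest.approx(4.14, abs=0.005)

    def test_linear_in_radius(self):
        a1 = womersley_number(2e-3, 2 * np.pi, 3.3e-6)
        a2 = womersley_number(4e-3, 2 * np.pi, 3.3e-6)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1e-3, 1.0, 1e-6), (1e-3, 1.0, 0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            womersley_number(*bad)


class TestFlowRatios:
    @pytest.mark.parametrize("alpha", [0.1, 1.0, 4.14, 10.0])
    def test_tube_ratio_matches_quadrature(self, alpha):
        R = 3e-3
        got = tube_flow_to_centerline_ratio(alpha, R)
        want = tube_ratio_quadrature(alpha, R) * R * R * np.pi / (
            np.pi * R * R
        )
        assert abs(got - want) / abs(want) < 1e-6

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 4.14, 10.0])
    def test_channel_ratio_matches_quadrature(self, alpha):
        a = 2e-3
        got = channel_flow_to_centerline_ratio(alpha, a)
        want = channel_ratio_quadrature(alpha, a)
        assert abs(got - want) / abs(want) < 1e-6

    def test_steady_limits_exact(self):
        R, a = 3e-3, 2e-3
        assert tube_flow_to_centerline_ratio(0.0, R) == np.pi * R * R / 2
        assert channel_flow_to_centerline_ratio(0.0, a) == pytest.approx(
            4 * a / 3, rel=1e-15
        )


class TestFlowFromCenterline:
    def test_poiseuille_limit(self):
        t = np.arange(64) / 64
        R = 3e-3
        u = VelocityWaveform(t=t, u=np.full(64, 0.5), T=1.0)
        Q = flow_from_centerline(u, R, FLUID)
        assert Q.Q == pytest.approx(np.pi * R * R * 0.5 / 2, rel=1e-12)

    def test_zero_in_zero_out(self):
        t = np.arange(64) / 64
        u = VelocityWaveform(t=t, u=np.zeros(64), T=1.0)
        Q = flow_from_centerline(u, 3e-3, FLUID)
        np.testing.assert_allclose(Q.Q, 0.0, atol=1e-15)

    def test_single_harmonic_matches_quadrature(self):
        t = np.arange(64) / 64
        R = 3e-3
        u = VelocityWaveform(t=t, u=0.5 * np.cos(2 * np.pi * t), T=1.0)
        Q = flow_from_centerline(u, R, FLUID, N=4)
        alpha = womersley_number(R, 2 * np.pi, FLUID.nu)
        ratio = tube_ratio_quadrature(alpha, R)  # per unit u_c
        q1 = 0.25 * ratio  # first-harmonic complex amplitude of u_c is 0.25
        want = 2 * (q1 * np.exp(2j * np.pi * t)).real
        assert np.max(np.abs(Q.Q - want)) / np.max(np.abs(want)) < 1e-6

    def test_round_trip_through_inlet_profile(self):
        # flow -> profile at r=0 must reproduce the centerline waveform
        t = np.arange(64) / 64
        R = 3e-3
        u = VelocityWaveform(
            t=t, u=0.4 + 0.3 * np.cos(2 * np.pi * t) + 0.1 *
            np.sin(4 * np.pi * t), T=1.0,
        )
        Q = flow_from_centerline(u, R, FLUID, N=6)
        uc = np.array(
            [inlet_profile(Q, R, FLUID, tt, np.array([0.0]), N=6)[0] for tt in t]
        )
        series = fourier_decompose(u, N=6)
        assert np.max(np.abs(uc - series(t))) / np.max(np.abs(u.u)) < 1e-6


class TestProfiles:
    def test_steady_profile_is_parabolic(self):
        R = 3e-3
        t = np.arange(64) / 64
        Q = FlowWaveform(t=t, Q=np.full(64, 2e-6), T=1.0)
        r = np.linspace(-R, R, 41)
        u = inlet_profile(Q, R, FLUID, 0.3, r)
        want = 2 * (2e-6 / (np.pi * R * R)) * (1 - (r / R) ** 2)
        np.testing.assert_allclose(u, want, rtol=1e-10, atol=1e-12)

    def test_no_slip_exact(self):
        R = 3e-3
        t = np.arange(64) / 64
        Q = FlowWaveform(t=t, Q=1e-6 * np.cos(2 * np.pi * t), T=1.0)
        u = inlet_profile(Q, R, FLUID, 0.17, np.array([-R, R]), N=4)
        assert u[0] == 0.0 and u[1] == 0.0

    def test_oscillatory_profile_integral_carries_flow(self):
        R = 3e-3
        t = np.arange(64) / 64
        Q = FlowWaveform(t=t, Q=1e-6 * np.cos(2 * np.pi * t), T=1.0)
        r = np.linspace(0, R, 20001)
        for tt in (0.0, 0.21, 0.5):
            u = inlet_profile(Q, R, FLUID, tt, r, N=4)
            got = 2 * np.pi * np.trapezoid(u * r, r)
            want = 2 * (0.5e-6 * np.exp(2j * np.pi * tt)).real
            assert got == pytest.approx(want, abs=1e-6 * 1e-6 + 1e-13)

    def test_high_alpha_profile_shows_annular_overshoot(self):
        # at alpha = 10 the oscillatory profile peaks off-center
        R = 10e-3 * np.sqrt(3.3e-6 / (2 * np.pi)) * 10  # alpha=10 at omega=2pi
        R = 10 * np.sqrt(FLUID.nu / (2 * np.pi))
        t = np.arange(64) / 64
        Q = FlowWaveform(t=t, Q=1e-6 * np.cos(2 * np.pi * t), T=1.0)
        r = np.linspace(0, R, 201)
        peak_off_center = False
        for tt in np.linspace(0, 1, 16, endpoint=False):
            u = inlet_profile(Q, R, FLUID, tt, r, N=2)
            i = np.argmax(np.abs(u))
            if 0.5 * R < r[i] < R:
                peak_off_center = True
        assert peak_off_center

    def test_channel_profile_integral(self):
        a = 2e-3
        t = np.arange(64) / 64
        q = FlowWaveform(t=t, Q=1e-4 * np.cos(2 * np.pi * t), T=1.0)
        y = np.linspace(-a, a, 20001)
        u = channel_profile(q, a, FLUID, 0.33, y, N=4)
        got = np.trapezoid(u, y)
        want = 2 * (0.5e-4 * np.exp(2j * np.pi * 0.33)).real
        assert got == pytest.approx(want, rel=1e-6)

    def test_out_of_lumen_coordinate_rejected(self):
        t = np.arange(64) / 64
        Q = FlowWaveform(t=t, Q=np.full(64, 1e-6), T=1.0)
        with pytest.raises(ValidationError):
            inlet_profile(Q, 3e-3, FLUID, 0.0, np.array([4e-3]))


class TestViscosity:
    def test_plasma_limit_and_monotonicity(self):
        mus = [viscosity_from_hematocrit(h) for h in (0.01, 0.30, 0.43)]
        assert mus[0] == pytest.approx(1.2e-3, rel=0.05)
        assert mus[0] < mus[1] < mus[2]

    def test_default_without_hematocrit(self):
        assert FluidProperties().mu == pytest.approx(3.5e-3)

    def test_hematocrit_overrides_mu(self):
        fl = FluidProperties(mu=1.0, hematocrit=0.35)
        assert fl.mu == pytest.approx(viscosity_from_hematocrit(0.35))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_domain(self, bad):
        with pytest.raises(ValidationError):
            viscosity_from_hematocrit(bad)


def test_channel_conversion_steady_ratio():
    a = 2e-3
    t = np.arange(64) / 64
    u = VelocityWaveform(t=t, u=np.full(64, 0.3), T=1.0)
    q = channel_flow_from_centerline(u, a, FLUID)
    assert q.Q == pytest.approx((2.0 / 3.0) * 2 * a * 0.3, rel=1e-12)
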