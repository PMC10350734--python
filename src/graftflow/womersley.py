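"""Closed-form pulsatile (Womersley) flow in tubes and plane channels.

Duplex ultrasound measures the *centerline* velocity; the CFD boundary
conditions need volumetric *flow*.  For fully developed pulsatile flow both
are linear functionals of the driving pressure-gradient harmonic, so their
ratio is an explicit function of the Womersley number

    alpha = R * sqrt(omega / nu),

which is how centerline velocities are converted to flow rates here.  Two
variants are provided: the circular tube (used for converting duplex
measurements, which are made in roughly circular vessels) and the plane
channel (the analytic counterpart of the planar 2D solver, used for its
inlet profile and for oracle tests).

Tube harmonic (Lambda = i^{3/2} alpha, J Bessel of first kind):

    u_hat(r)   = A [1 - J0(Lambda r/R) / J0(Lambda)]
    u_c        = A [1 - 1/J0(Lambda)]
    Q          = A pi R^2 [1 - 2 J1(Lambda) / (Lambda J0(Lambda))]

Channel harmonic (half-width a, lam = i^{1/2} alpha):

    u_hat(y)   = A [1 - cosh(lam y/a) / cosh(lam)]
    u_c        = A [1 - 1/cosh(lam)]
    q          = A 2a [1 - tanh(lam)/lam]        (per unit depth)

The steady (n = 0) limits are the Poiseuille ratios Q/u_c = pi R^2 / 2 and
q/u_c = (2/3) * 2a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .errors import ValidationError
from .waveforms import (
    FlowWaveform,
    HarmonicSeries,
    VelocityWaveform,
    fourier_decompose,
)

__all__ = [
    "FluidProperties",
    "womersley_number",
    "viscosity_from_hematocrit",
    "tube_flow_to_centerline_ratio",
    "channel_flow_to_centerline_ratio",
    "flow_from_centerline",
    "channel_flow_from_centerline",
    "inlet_profile",
    "channel_profile",
    "tube_profile",
]

DEFAULT_VISCOSITY = 3.5e-3  # Pa s, whole blood at high shear
DEFAULT_DENSITY = 1060.0  # kg/m^3
PLASMA_VISCOSITY = 1.2e-3  # Pa s


def viscosity_from_hematocrit(
    H: float, mu_plasma: float = PLASMA_VISCOSITY
) -> float:
    """Whole-blood viscosity from hematocrit.

    A quadratic hardened-suspension relation
    ``mu = mu_plasma * (1 + 2.5 H + 7.35 H^2)`` anchored at the Einstein
    dilute limit; monotone increasing on (0, 1) and configurable through
    ``mu_plasma``.  At H = 0.45 it gives ~3.3 mPa s, the usual high-shear
    whole-blood value.
    """
    if not (0.0 < H < 1.0):
        raise ValidationError(f"hematocrit must be in (0, 1), got {H}")
    return mu_plasma * (1.0 + 2.5 * H + 7.35 * H * H)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid model of blood.

    If ``hematocrit`` is given, viscosity is derived from it via
    :func:`viscosity_from_hematocrit`; otherwise ``mu`` is used directly
    (default 3.5 mPa s).
    """

    rho: float = DEFAULT_DENSITY
    mu: float = DEFAULT_VISCOSITY
    hematocrit: float | None = None

    def __post_init__(self):
        if self.rho <= 0:
            raise ValidationError("density must be positive")
        if self.hematocrit is not None:
            object.__setattr__(
                self, "mu", viscosity_from_hematocrit(self.hematocrit)
            )
        if self.mu <= 0:
            raise ValidationError("viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity m^2/s."""
        return self.mu / self.rho


def womersley_number(R: float, omega: float, nu: float) -> float:
    """alpha = R sqrt(omega/nu); zero iff omega is zero."""
    if R <= 0:
        raise ValidationError("radius must be positive")
    if nu <= 0:
        raise ValidationError("kinematic viscosity must be positive")
    if omega < 0:
        raise ValidationError("angular frequency must be >= 0")
    return R * np.sqrt(omega / nu)


def _Lambda(alpha: float) -> complex:
    """Tube argument i^{3/2} alpha."""
    return alpha * np.exp(1j * 3.0 * np.pi / 4.0)


def _lam(alpha: float) -> complex:
    """Channel argument i^{1/2} alpha."""
    return alpha * np.exp(1j * np.pi / 4.0)


def tube_flow_to_centerline_ratio(alpha: float, R: float) -> complex:
    """Q_n / u_c,n for a circular tube of radius R at Womersley number alpha.

    Steady limit (alpha = 0): pi R^2 / 2.
    """
    if alpha == 0.0:
        return np.pi * R * R / 2.0
    L = _Lambda(alpha)
    j0 = jv(0, L)
    if abs(j0) < 1e-300:
        raise FloatingPointError("J0(Lambda) vanished; unphysical alpha")
    q_term = 1.0 - 2.0 * jv(1, L) / (L * j0)
    uc_term = 1.0 - 1.0 / j0
    return np.pi * R * R * q_term / uc_term


def channel_flow_to_centerline_ratio(alpha: float, a: float) -> complex:
    """q_n / u_c,n (per unit depth) for a channel of half-width a.

    Steady limit: (2/3) * 2a.
    """
    if alpha == 0.0:
        return 4.0 * a / 3.0
    lam = _lam(alpha)
    q_term = 1.0 - np.tanh(lam) / lam
    uc_term = 1.0 - 1.0 / np.cosh(lam)
    return 2.0 * a * q_term / uc_term


def _harmonics_of(w, N):
    if isinstance(w, HarmonicSeries):
        return w
    return fourier_decompose(w, N=N)


def flow_from_centerline(
    u: VelocityWaveform, R: float, fluid: FluidProperties, N: int = 10
) -> FlowWaveform:
    """Convert a centerline-velocity waveform to volumetric flow (tube).

    Harmonic-by-harmonic application of the tube Womersley ratio, then real
    resynthesis at the input sample times.  The steady component uses the
    Poiseuille ratio pi R^2 / 2 (centerline = twice the mean velocity).
    """
    if R <= 0:
        raise ValidationError("radius must be positive")
    series = _harmonics_of(u, N)
    omega0 = series.omega0
    qc = np.empty_like(series.coeffs)
    for n in range(series.coeffs.size):
        alpha = womersley_number(R, n * omega0, fluid.nu)
        qc[n] = series.coeffs[n] * tube_flow_to_centerline_ratio(alpha, R)
    qseries = HarmonicSeries(omega0=omega0, coeffs=qc)
    return FlowWaveform(t=u.t, Q=qseries(u.t), T=u.T, site=u.site)


def channel_flow_from_centerline(
    u: VelocityWaveform, a: float, fluid: FluidProperties, N: int = 10
) -> FlowWaveform:
    """Channel variant of :func:`flow_from_centerline` (flow per unit depth)."""
    if a <= 0:
        raise ValidationError("half-width must be positive")
    series = _harmonics_of(u, N)
    omega0 = series.omega0
    qc = np.empty_like(series.coeffs)
    for n in range(series.coeffs.size):
        alpha = womersley_number(a, n * omega0, fluid.nu)
        qc[n] = series.coeffs[n] * channel_flow_to_centerline_ratio(alpha, a)
    qseries = HarmonicSeries(omega0=omega0, coeffs=qc)
    return FlowWaveform(t=u.t, Q=qseries(u.t), T=u.T, site=u.site)


def _profile_from_flow_harmonics(coeffs, omega0, nu, xi, size_param, kind):
    """Velocity profile snapshot builder shared by tube and channel.

    ``xi`` is the normalized transverse coordinate r/R (tube) or y/a
    (channel); returns complex harmonic profiles, one row per harmonic.
    """
    prof = np.zeros((coeffs.size,) + xi.shape, dtype=complex)
    for n in range(coeffs.size):
        if n == 0:
            if kind == "tube":
                shape = 2.0 * (1.0 - xi**2)  # mean-velocity-normalized
                area = np.pi * size_param**2
            else:
                shape = 1.5 * (1.0 - xi**2)
                area = 2.0 * size_param
            prof[0] = coeffs[0].real / area * shape
            continue
        alpha = size_param * np.sqrt(n * omega0 / nu)
        if kind == "tube":
            L = _Lambda(alpha)
            shape = 1.0 - jv(0, L * xi) / jv(0, L)
            integral = np.pi * size_param**2 * (1.0 - 2.0 * jv(1, L) / (L * jv(0, L)))
        else:
            lam = _lam(alpha)
            shape = 1.0 - np.cosh(lam * xi) / np.cosh(lam)
            integral = 2.0 * size_param * (1.0 - np.tanh(lam) / lam)
        prof[n] = coeffs[n] / integral * shape
    return prof


def _profile(Q, size_param, fluid, t, coord, N, kind):
    coord = np.asarray(coord, dtype=float)
    if np.any(np.abs(coord) > size_param * (1.0 + 1e-12)):
        raise ValidationError("transverse coordinate outside the lumen")
    series = _harmonics_of(Q, N)
    xi = np.clip(coord / size_param, -1.0, 1.0)
    prof = _profile_from_flow_harmonics(
        series.coeffs, series.omega0, fluid.nu, xi, size_param, kind
    )
    t = np.asarray(t, dtype=float)
    if t.ndim != 0:
        raise ValidationError("t must be a scalar time")
    out = np.real(prof[0]).astype(float)
    for n in range(1, prof.shape[0]):
        out = out + 2.0 * np.real(prof[n] * np.exp(1j * n * series.omega0 * float(t)))
    # enforce exact no-slip at the wall nodes
    out[np.isclose(np.abs(xi), 1.0, rtol=0.0, atol=1e-12)] = 0.0
    return out


def inlet_profile(Q, R: float, fluid: FluidProperties, t: float, r, N: int = 10):
    """Womersley tube velocity profile u(r, t) carrying flow waveform ``Q``.

    The cross-sectional integral 2 pi int u r dr reproduces the band-limited
    Q(t); u(+-R, t) = 0 exactly.
    """
    if R <= 0:
        raise ValidationError("radius must be positive")
    return _profile(Q, R, fluid, np.asarray(t, dtype=float), r, N, "tube")


tube_profile = inlet_profile


def channel_profile(q, a: float, fluid: FluidProperties, t: float, y, N: int = 10):
    """Channel Womersley profile u(y, t) carrying per-depth flow ``q``."""
    if a <= 0:
        raise ValidationError("half-width must be positive")
    return _profile(q, a, fluid, np.asarray(t, dtype=float), y, N, "channel")


def channel_profile_harmonics(q, a: float, fluid: FluidProperties, y, N: int = 10):
    """Complex harmonic channel profiles (rows: harmonic 0..N) at coordinates y.

    Used by the solver to evaluate the inlet Dirichlet data at arbitrary
    times as  u(y,t) = Re(P0) + sum_n 2 Re(P_n e^{i n w0 t}).
    """
    series = _harmonics_of(q, N)
    y = np.asarray(y, dtype=float)
    xi = np.clip(y / a, -1.0, 1.0)
    prof = _profile_from_flow_harmonics(
        series.coeffs, series.omega0, fluid.nu, xi, a, "channel"
    )
    wall = np.isclose(np.abs(xi), 1.0, rtol=0.0, atol=1e-12)
    prof[:, wall] = 0.0
    return series.omega0, prof
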