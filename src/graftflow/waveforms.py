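"""One-cycle periodic velocity and flow waveforms.

Femoral duplex ultrasound reports the centerline velocity over one cardiac
cycle.  A healthy femoral waveform is *triphasic* — a sharp forward systolic
peak, an early-diastolic reverse lobe, and a small late forward wave — while
a post-stenotic or high-resistance-failure waveform degenerates to
*monophasic* forward-only flow.  The distinction matters hemodynamically:
the reverse phase washes out regions of separated, slowly recirculating
flow, and its absence is one of the mechanisms behind low wall shear stress
in failing endografts.

Waveforms are treated as T-periodic sample vectors (no duplicated endpoint)
with a Fourier-series representation used harmonic-by-harmonic downstream
(pulsatile tube/channel theory is a per-harmonic closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "VelocityWaveform",
    "FlowWaveform",
    "HarmonicSeries",
    "synth_duplex_waveform",
    "fourier_decompose",
    "read_waveform_csv",
    "write_waveform_csv",
]

MIN_SAMPLES = 32


def _check_sampling(t: np.ndarray, T: float) -> None:
    if T <= 0:
        raise ValidationError(f"cardiac period must be positive, got T={T}")
    if t.ndim != 1 or t.size < MIN_SAMPLES:
        raise ValidationError(
            f"waveform needs >= {MIN_SAMPLES} samples per cycle, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValidationError("sample times must be strictly increasing")
    if t[0] < 0 or t[-1] >= T:
        raise ValidationError("sample times must lie in [0, T)")


@dataclass(frozen=True)
class VelocityWaveform:
    """Centerline velocity over one cardiac cycle at a named site.

    Parameters
    ----------
    t : sample times in seconds, strictly increasing, in ``[0, T)``.
    u : centerline velocity in m/s at those times.
    T : cardiac period in seconds.  The signal is treated as T-periodic.
    site : measurement site label, conventionally ``CFA``/``SFA``/``DFA``.
    """

    t: np.ndarray
    u: np.ndarray
    T: float
    site: str = "CFA"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "u", u)
        _check_sampling(t, self.T)
        if u.shape != t.shape:
            raise ValidationError("t and u must have the same shape")
        if not np.all(np.isfinite(u)):
            raise ValidationError("velocity samples must be finite")

    @property
    def samples(self) -> np.ndarray:
        return self.u

    def mean(self) -> float:
        return float(np.mean(self.u))


@dataclass(frozen=True)
class FlowWaveform:
    """Volumetric flow over one cycle.

    ``Q`` is in m^3/s for circular-tube flows and m^2/s (per unit depth) for
    the planar channel analogue; the carrier is unit-agnostic.
    """

    t: np.ndarray
    Q: np.ndarray
    T: float
    site: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "Q", Q)
        _check_sampling(t, self.T)
        if Q.shape != t.shape:
            raise ValidationError("t and Q must have the same shape")
        if not np.all(np.isfinite(Q)):
            raise ValidationError("flow samples must be finite")

    @property
    def samples(self) -> np.ndarray:
        return self.Q

    def mean(self) -> float:
        return float(np.mean(self.Q))

    def scaled(self, factor: float) -> "FlowWaveform":
        return replace(self, Q=self.Q * factor)


@dataclass(frozen=True)
class HarmonicSeries:
    """Truncated Fourier series of a T-periodic real signal.

    ``coeffs[n]`` is the complex amplitude of harmonic ``n`` with the
    convention  x(t) = c0 + sum_{n>=1} 2 Re(c_n exp(i n omega0 t)),
    so ``coeffs[0]`` is the cycle mean (real).
    """

    omega0: float
    coeffs: np.ndarray = field(repr=False)

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=complex)
        object.__setattr__(self, "coeffs", c)
        if self.omega0 <= 0:
            raise ValidationError("fundamental frequency must be positive")
        if abs(c[0].imag) > 1e-12 * (1.0 + abs(c[0])):
            raise ValidationError("DC coefficient must be real")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.size - 1

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega0

    def __call__(self, t) -> np.ndarray:
        """Evaluate the band-limited reconstruction at times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.coeffs[0].real, dtype=float)
        for n in range(1, self.coeffs.size):
            out += 2.0 * (self.coeffs[n] * np.exp(1j * n * self.omega0 * t)).real
        return out

    def mean_square(self) -> float:
        """Mean square of the band-limited signal (Parseval)."""
        c = self.coeffs
        return float(c[0].real ** 2 + 2.0 * np.sum(np.abs(c[1:]) ** 2))


# -- synthesis ---------------------------------------------------------------

# Relative timing of the three lobes of a triphasic femoral waveform, as
# fractions of the cardiac period: forward systolic peak, early-diastolic
# reverse lobe, small late forward wave.
_TRIPHASIC_CENTERS = (0.12, 0.30, 0.55)
_TRIPHASIC_WIDTHS = (0.045, 0.050, 0.090)  # gaussian sigma / T
_LATE_WAVE_FRACTION = 0.18  # late forward lobe height as fraction of PSV

# Monophasic (tardus-parvus-like) template: slow broad systolic upstroke plus
# sustained forward diastolic flow; everywhere non-negative.
_MONO_CENTER, _MONO_WIDTH, _MONO_BASELINE = 0.20, 0.10, 0.05


def _periodic_gaussian(t, T, center, sigma):
    """Gaussian lobe wrapped onto the circle (3 nearest images suffice)."""
    acc = np.zeros_like(t)
    for k in (-1, 0, 1):
        acc += np.exp(-0.5 * ((t - center + k * T) / sigma) ** 2)
    return acc


def synth_duplex_waveform(
    psv: float,
    reverse_fraction: float,
    T: float,
    phase: str = "triphasic",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 200,
    site: str = "CFA",
) -> VelocityWaveform:
    """Synthesize a duplex-like centerline velocity waveform.

    Parameters
    ----------
    psv : peak systolic velocity, m/s (> 0).
    reverse_fraction : reverse-lobe peak as a fraction of ``psv``; must be 0
        for monophasic waveforms.
    T : cardiac period, s.
    phase : ``"triphasic"`` or ``"monophasic"``.
    noise_sd : standard deviation of additive Gaussian sample noise, m/s.
    seed : RNG seed; the output is deterministic given the seed.
    """
    if psv <= 0:
        raise ValidationError("psv must be positive")
    if T <= 0:
        raise ValidationError("cardiac period must be positive")
    if reverse_fraction < 0:
        raise ValidationError("reverse_fraction must be >= 0")
    if phase not in ("triphasic", "monophasic"):
        raise ValidationError(f"unknown phase {phase!r}")
    if phase == "monophasic" and reverse_fraction > 0:
        raise ValidationError("monophasic waveforms cannot have a reverse lobe")

    t = np.arange(n_samples) * (T / n_samples)
    if phase == "triphasic":
        c1, c2, c3 = (c * T for c in _TRIPHASIC_CENTERS)
        s1, s2, s3 = (s * T for s in _TRIPHASIC_WIDTHS)
        u = (
            psv * _periodic_gaussian(t, T, c1, s1)
            - reverse_fraction * psv * _periodic_gaussian(t, T, c2, s2)
            + _LATE_WAVE_FRACTION * psv * _periodic_gaussian(t, T, c3, s3)
        )
    else:
        u = psv * (
            _periodic_gaussian(t, T, _MONO_CENTER * T, _MONO_WIDTH * T)
            + _MONO_BASELINE
        ) / (1.0 + _MONO_BASELINE)
        u = np.maximum(u, 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise_sd, size=u.shape)
        if phase == "monophasic":
            u = np.maximum(u, 0.0)

    return VelocityWaveform(t=t, u=u, T=T, site=site)


# -- Fourier analysis --------------------------------------------------------


def fourier_decompose(w, N: int = 10) -> HarmonicSeries:
    """Decompose a waveform into its first ``N`` harmonics.

    Uses the DFT of the uniformly resampled signal; for the uniformly sampled
    waveforms produced in this package this is exact band-limited analysis.
    ``N`` must be below the Nyquist index of the sampling.
    """
    x = np.asarray(w.samples, dtype=float)
    n = x.size
    if N < 0:
        raise ValidationError("N must be non-negative")
    if N >= n // 2:
        raise ValidationError(
            f"N={N} harmonics would alias at {n} samples/cycle (need N < n/2)"
        )
    dt = np.diff(w.t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12 * w.T):
        # non-uniform sampling: resample onto a uniform grid by periodic
        # linear interpolation before the DFT
        tu = np.arange(n) * (w.T / n)
        tp = np.concatenate([w.t, [w.t[0] + w.T]])
        xp = np.concatenate([x, [x[0]]])
        x = np.interp(tu, tp, xp)
        t0 = 0.0
    else:
        t0 = w.t[0]
    c = np.fft.rfft(x) / n
    c = c[: N + 1].copy()
    omega0 = 2.0 * np.pi / w.T
    if t0 != 0.0:
        # refer phases to t = 0
        c *= np.exp(-1j * np.arange(N + 1) * omega0 * t0)
    c[0] = c[0].real
    return HarmonicSeries(omega0=omega0, coeffs=c)


# -- CSV I/O -----------------------------------------------------------------

_TIME_COL = "time_s"
_VEL_COL = "velocity_m_per_s"


def write_waveform_csv(w: VelocityWaveform, path) -> None:
    """Write a waveform as a two-column CSV (``time_s, velocity_m_per_s``)."""
    df = pd.DataFrame({_TIME_COL: w.t, _VEL_COL: w.u})
    df.to_csv(path, index=False, float_format="%.12g")


def read_waveform_csv(path, site: str = "CFA") -> VelocityWaveform:
    """Read a waveform CSV; the period is the last sample time plus one step."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse waveform CSV {path}: {exc}") from exc
    for col in (_TIME_COL, _VEL_COL):
        if col not in df.columns:
            raise FormatError(f"waveform CSV {path} lacks required column {col!r}")
    t = df[_TIME_COL].to_numpy(dtype=float)
    u = df[_VEL_COL].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise FormatError(f"waveform CSV {path}: time column must be strictly increasing")
    T = float(t[-1] + np.median(np.diff(t)) - t[0])
    try:
        return VelocityWaveform(t=t - t[0], u=u, T=T, site=site)
    except ValidationError as exc:
        raise FormatError(f"waveform CSV {path}: {exc}") from exc
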