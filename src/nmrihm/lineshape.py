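"""Time-domain pseudo-Voigt signal model and its frequency-domain spectrum.

A single NMR line is modeled in the time domain as an oscillation at
offset ``nu`` (Hz from the carrier) under a decay envelope that mixes a
Lorentzian-producing exponential and a Gaussian-producing squared
exponential::

    s(t) = K * exp(2*pi*i*nu*t) * [(1-beta)*exp(-pi*G*t)
                                   + beta*exp(-pi^2*G^2*t^2 / (4*ln 2))]

Both envelopes are parameterized so the frequency-domain line has the
same full width at half maximum ``G`` (Hz); ``beta`` interpolates between
a pure Lorentzian (beta=0) and a pure Gaussian (beta=1) — the standard
pseudo-Voigt mix.  Discrete Fourier transformation with the customary
first-point halving yields an absorptive real spectrum whose integral
over frequency equals s(0) = K, the basis of quantitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Peak",
    "AcquisitionGrid",
    "Spectrum",
    "ppm_to_hz",
    "hz_to_ppm",
    "fid_signal",
    "fid_signals",
    "spectrum_from_fid",
    "lorentzian_window_fraction",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Peak:
    """One pseudo-Voigt line.

    Parameters
    ----------
    amplitude : float
        Relative intensity K (arbitrary units); equals the spectral
        integral of the line.  Must be >= 0.
    offset_hz : float
        Frequency offset nu from the carrier, in Hz.
    fwhm_hz : float
        Full width at half maximum Gamma of the frequency-domain line,
        in Hz.  Must be > 0.
    gauss_fraction : float
        Fraction of Gaussian character beta in [0, 1]; 0 is pure
        Lorentzian, 1 pure Gaussian.
    """

    amplitude: float
    offset_hz: float
    fwhm_hz: float
    gauss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.amplitude >= 0):
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (self.fwhm_hz > 0):
            raise ValueError(f"fwhm_hz must be > 0, got {self.fwhm_hz}")
        if not (0.0 <= self.gauss_fraction <= 1.0):
            raise ValueError(
                f"gauss_fraction must be in [0, 1], got {self.gauss_fraction}"
            )


@dataclass(frozen=True)
class AcquisitionGrid:
    """Sampling grid of a 1D acquisition.

    The time axis is t_j = j / spectral_width for j = 0 .. n_points-1
    (dwell time 1/SW).  The derived ppm axis is strictly decreasing
    (high ppm on the left, NMR convention) and spans
    carrier_ppm +- SW / (2 * SF).
    """

    spectrometer_frequency: float  # MHz
    carrier_ppm: float
    spectral_width: float  # Hz
    n_points: int

    def __post_init__(self) -> None:
        if not (self.spectrometer_frequency > 0):
            raise ValueError("spectrometer_frequency must be > 0")
        if not (self.spectral_width > 0):
            raise ValueError("spectral_width must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) / self.spectral_width

    @property
    def freq_axis_hz(self) -> np.ndarray:
        """Frequency axis (Hz from carrier), descending to match ppm axis."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell))
        return f[::-1]

    @property
    def ppm_axis(self) -> np.ndarray:
        """Strictly decreasing chemical-shift axis in ppm."""
        return self.carrier_ppm + self.freq_axis_hz / self.spectrometer_frequency

    @property
    def ppm_step(self) -> float:
        """Magnitude of the ppm spacing between adjacent grid points."""
        return self.spectral_width / (self.n_points * self.spectrometer_frequency)

    def contains_offset(self, offset_hz: float) -> bool:
        """Whether a frequency offset falls inside the spectral window."""
        return -self.spectral_width / 2 <= offset_hz < self.spectral_width / 2


@dataclass
class Spectrum:
    """Real (absorptive) spectrum on an acquisition grid.

    ``intensities`` is aligned with ``grid.ppm_axis`` (descending ppm).
    """

    grid: AcquisitionGrid
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensities length {self.intensities.shape} does not match "
                f"grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def ppm_axis(self) -> np.ndarray:
        return self.grid.ppm_axis

    def integral(self, indices: np.ndarray | None = None) -> float:
        """Trapezoidal integral over the frequency axis in Hz.

        With the normalization used by :func:`spectrum_from_fid`, the
        full-axis integral of a single line equals its amplitude K.
        """
        hz = self.grid.freq_axis_hz
        y = self.intensities
        if indices is not None:
            hz = hz[indices]
            y = y[indices]
        # axis is descending in Hz; integrate on the ascending reversal
        return float(np.trapezoid(y[::-1], hz[::-1]))


def ppm_to_hz(delta: float | np.ndarray, grid: AcquisitionGrid):
    """Chemical shift (ppm) -> frequency offset from the carrier (Hz)."""
    return (np.asarray(delta) - grid.carrier_ppm) * grid.spectrometer_frequency


def hz_to_ppm(offset: float | np.ndarray, grid: AcquisitionGrid):
    """Frequency offset from the carrier (Hz) -> chemical shift (ppm)."""
    return grid.carrier_ppm + np.asarray(offset) / grid.spectrometer_frequency


def _envelopes(fwhm: np.ndarray, beta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pseudo-Voigt decay envelopes, shape (n_peaks, n_times)."""
    fwhm = fwhm[:, None]
    beta = beta[:, None]
    lor = np.exp(-math.pi * fwhm * t)
    gau = np.exp(-(math.pi**2) * fwhm**2 * t**2 / (4.0 * _LN2))
    return (1.0 - beta) * lor + beta * gau


def fid_signals(
    amplitudes: np.ndarray,
    offsets_hz: np.ndarray,
    fwhms_hz: np.ndarray,
    gauss_fractions: np.ndarray,
    grid: AcquisitionGrid,
) -> np.ndarray:
    """Sum of many pseudo-Voigt FIDs, vectorized over peaks.

    All four parameter arrays must share one length P; returns the
    complex time series of length grid.n_points summing the P signals.
    """
    K = np.asarray(amplitudes, dtype=float)
    nu = np.asarray(offsets_hz, dtype=float)
    G = np.asarray(fwhms_hz, dtype=float)
    b = np.asarray(gauss_fractions, dtype=float)
    if not (K.shape == nu.shape == G.shape == b.shape):
        raise ValueError("peak parameter arrays must share one shape")
    if K.size == 0:
        return np.zeros(grid.n_points, dtype=complex)
    if np.any(K < 0):
        raise ValueError("amplitudes must be >= 0")
    if np.any(G <= 0):
        raise ValueError("fwhms must be > 0")
    if np.any((b < 0) | (b > 1)):
        raise ValueError("gauss_fractions must be in [0, 1]")
    t = grid.times
    phase = np.exp(2j * math.pi * nu[:, None] * t)
    env = _envelopes(G, b, t)
    return np.einsum("p,pt->t", K, phase * env)


def fid_signal(peak: Peak, grid: AcquisitionGrid) -> np.ndarray:
    """Complex time-domain signal of one line; s(0) = K exactly."""
    return fid_signals(
        np.array([peak.amplitude]),
        np.array([peak.offset_hz]),
        np.array([peak.fwhm_hz]),
        np.array([peak.gauss_fraction]),
        grid,
    )


def spectrum_from_fid(fid: np.ndarray, grid: AcquisitionGrid) -> Spectrum:
    """Fourier transform a FID to an absorptive real spectrum.

    The first time point is halved (the t=0 sample straddles the
    one-sided acquisition boundary), the DFT is scaled by 2*dwell so the
    trapezoidal integral over frequency equals s(0), and the result is
    reordered onto the descending ppm axis.
    """
    fid = np.asarray(fid, dtype=complex)
    if fid.shape != (grid.n_points,):
        raise ValueError(
            f"fid length {fid.shape} does not match grid n_points {grid.n_points}"
        )
    work = fid.copy()
    work[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(work)) * (2.0 * grid.dwell)
    return Spectrum(grid, spec.real[::-1])


def lorentzian_window_fraction(width_in_fwhm: float) -> float:
    """Fraction of a Lorentzian line's area inside a centered window.

    The window's total width is ``width_in_fwhm`` times the line's FWHM;
    the enclosed area fraction is (2/pi)*arctan(width_in_fwhm).  At 64
    FWHM the window captures 99.0% of the area — the classical rule for
    quantitative integration of NMR signals.
    """
    if width_in_fwhm < 0:
        raise ValueError("window width must be >= 0")
    return (2.0 / math.pi) * math.atan(width_in_fwhm)
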