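"""Continuous wavelet transform, phase transform and synchrosqueezing.

The CWT uses an analytic Morlet wavelet evaluated in the frequency domain,

    W(a, b) = IFFT[ X(xi) * sqrt(a) * conj(psi_hat(a * xi)) ](b),

with the ``a**(-1/2)`` amplitude normalization (so the frequency-domain
kernel carries ``sqrt(a)``).  Scales map to pseudo-frequencies through
``f = f_c / (a * dt)``.  The phase transform estimates a local
instantaneous frequency

    omega(a, b) = Im[ d/db W(a, b) / (2 pi W(a, b)) ]

where the time derivative comes from a second transform with the
frequency-domain multiplier ``i 2 pi xi`` (a finite-difference fallback is
used only as an independent test oracle).  Synchrosqueezing then reassigns
each coefficient to the linear frequency bin nearest omega with the
log-uniform scale measure ``da/a = ln(2)/voices``:

    T(xi_l, b) = sum_{k : omega(a_k, b) in bin l} W(a_k, b) * ln(2)/voices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "WaveletSpec",
    "ScaleGrid",
    "CWTMap",
    "PhaseMap",
    "SWTMap",
    "make_scale_grid",
    "cwt",
    "phase_transform",
    "synchrosqueeze",
    "swt",
    "ridge",
    "interpolate_cwt_magnitude",
]

#: Scale measure for a log grid: da/a = ln(2) / voices_per_octave.
LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class WaveletSpec:
    """Analytic Morlet wavelet.

    ``psi(t) = exp(i 2 pi f_c t) exp(-t^2 / (2 sigma^2))`` with the
    frequency-domain form ``psi_hat(xi) = sigma sqrt(2 pi)
    exp(-2 pi^2 sigma^2 (xi - f_c)^2)`` restricted to ``xi > 0``.  The
    default ``sigma = 0.5 / f_c`` (about three cycles inside the
    +-3 sigma envelope) keeps the scaled wavelet's support short enough
    that boundary transients from the reflect padding do not leak across
    interior columns at the largest scales; a longer wavelet can be
    requested via ``time_spread``.
    """

    family: str = "analytic_morlet"
    center_frequency: float = 1.0
    time_spread: float | None = None  # sigma; defaults to 0.5 / center_frequency

    def __post_init__(self) -> None:
        if self.family != "analytic_morlet":
            raise ValueError(f"unsupported wavelet family {self.family!r}")
        if self.center_frequency <= 0:
            raise ValueError("center frequency must be positive")
        if self.time_spread is not None and self.time_spread <= 0:
            raise ValueError("time spread must be positive")

    @property
    def sigma(self) -> float:
        return (
            self.time_spread
            if self.time_spread is not None
            else 0.5 / self.center_frequency
        )

    def freq_response(self, xi: np.ndarray) -> np.ndarray:
        """``psi_hat`` on an array of frequencies (cycles per unit time of
        the wavelet's own clock); zero for ``xi <= 0`` (analytic)."""
        s = self.sigma
        out = s * np.sqrt(2.0 * np.pi) * np.exp(
            -2.0 * np.pi**2 * s**2 * (xi - self.center_frequency) ** 2
        )
        return np.where(xi > 0, out, 0.0)

    def time_response(self, t: np.ndarray) -> np.ndarray:
        s = self.sigma
        return np.exp(1j * 2 * np.pi * self.center_frequency * t) * np.exp(
            -(t**2) / (2 * s**2)
        )

    def support_samples(self, scale: float, n_sigma: float = 5.0) -> int:
        """Effective one-sided support of the scaled wavelet, in samples."""
        return int(np.ceil(n_sigma * self.sigma * scale))


@dataclass(frozen=True)
class ScaleGrid:
    """Logarithmic scale grid; ``freqs`` descend as ``scales`` ascend."""

    scales: np.ndarray  # samples, ascending
    freqs: np.ndarray  # Hz, descending, f_k = f_c * fs / a_k
    voices_per_octave: int
    fmin: float
    fmax: float
    fs: float

    @property
    def n_scales(self) -> int:
        return len(self.scales)


def make_scale_grid(
    fs: float,
    fmin: float,
    fmax: float,
    voices_per_octave: int = 8,
    wavelet: WaveletSpec | None = None,
) -> ScaleGrid:
    """Log-spaced grid ``f_k = fmin * 2**(k/voices)`` for ``k = 0..K`` with
    ``K = floor(voices * log2(fmax / fmin))``; scales ``a_k = f_c * fs / f_k``
    in samples."""
    if not (0 < fmin <= fmax):
        raise ValueError("need 0 < fmin <= fmax")
    if fmax > fs / 2:
        raise ValueError(f"fmax={fmax} exceeds the Nyquist frequency {fs / 2}")
    if voices_per_octave < 1:
        raise ValueError("voices_per_octave must be >= 1")
    wavelet = wavelet or WaveletSpec()
    if fmin == fmax:
        freqs = np.array([fmax], dtype=float)
    else:
        k_max = int(np.floor(voices_per_octave * np.log2(fmax / fmin)))
        freqs = fmin * 2.0 ** (np.arange(k_max + 1) / voices_per_octave)
    freqs = freqs[::-1].copy()  # descending
    scales = wavelet.center_frequency * fs / freqs
    return ScaleGrid(
        scales=scales,
        freqs=freqs,
        voices_per_octave=voices_per_octave,
        fmin=fmin,
        fmax=fmax,
        fs=fs,
    )


@dataclass
class CWTMap:
    coeffs: np.ndarray  # (n_scales, n_times) complex
    d_coeffs: np.ndarray | None  # time derivative dW/db (per second), or None
    grid: ScaleGrid
    times: np.ndarray  # seconds

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[1]

    def scale_support(self, wavelet: WaveletSpec | None = None) -> np.ndarray:
        """Per-scale one-sided boundary extent in samples (columns closer
        than this to either edge are boundary-affected)."""
        w = wavelet or WaveletSpec()
        return np.array([w.support_samples(a, 3.0) for a in self.grid.scales])


@dataclass
class PhaseMap:
    omega: np.ndarray  # Hz, zero where invalid
    valid_mask: np.ndarray  # bool
    gamma: float


@dataclass
class SWTMap:
    coeffs: np.ndarray  # (n_freqs, n_times) complex
    freqs: np.ndarray  # Hz, ascending linear grid
    times: np.ndarray  # seconds

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[1]


def _validate_signal(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D array of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("signal contains NaN or Inf")
    return x


def cwt(
    signal: np.ndarray,
    wavelet: WaveletSpec | None = None,
    grid: ScaleGrid | None = None,
    *,
    fs: float | None = None,
    pad: bool = True,
    derivative: bool = True,
) -> CWTMap:
    """FFT-based CWT of a real signal on a log scale grid.

    The signal is reflect-padded by the largest wavelet support on each
    side (boundary columns are retained; ``CWTMap.scale_support`` exposes
    their extent).  With ``derivative=True`` a second transform with the
    ``i 2 pi xi`` multiplier provides ``dW/db`` for the phase transform.
    """
    x = _validate_signal(signal)
    wavelet = wavelet or WaveletSpec()
    if grid is None:
        if fs is None:
            raise ValueError("either grid or fs is required")
        grid = make_scale_grid(fs, 0.5, min(50.0, fs / 2), wavelet=wavelet)
    n = x.size

    if pad:
        p = min(int(max(wavelet.support_samples(a) for a in grid.scales)), 8 * n)
        xp = np.pad(x, p, mode="reflect")
    else:
        p = 0
        xp = x
    m = next_fast_len(xp.size)
    xi = np.fft.fftfreq(m)  # cycles / sample
    X = fft(xp, m)

    # (n_scales, m) kernel: sqrt(a) * psi_hat(a * xi); psi_hat real, analytic.
    a = grid.scales[:, None]
    kern = np.sqrt(a) * wavelet.freq_response(a * xi[None, :])
    W = ifft(X[None, :] * kern, axis=1)[:, p : p + n]
    d_coeffs = None
    if derivative:
        mult = 1j * 2.0 * np.pi * xi * grid.fs  # d/db in per-second units
        dW = ifft(X[None, :] * kern * mult[None, :], axis=1)[:, p : p + n]
        d_coeffs = np.ascontiguousarray(dW)
    return CWTMap(
        coeffs=np.ascontiguousarray(W),
        d_coeffs=d_coeffs,
        grid=grid,
        times=np.arange(n) / grid.fs,
    )


def phase_transform(cwt_map: CWTMap, gamma: float | None = None) -> PhaseMap:
    """Instantaneous-frequency map ``omega = Im[(dW/db) / (2 pi W)]`` in Hz.

    Entries with ``|W| <= gamma`` are masked invalid (``gamma`` defaults to
    ``1e-8 * max|W|``).  If the map lacks a stored derivative, ``dW/db`` is
    computed spectrally along each scale row.
    """
    if gamma is not None and gamma < 0:
        raise ValueError("gamma must be non-negative")
    W = cwt_map.coeffs
    absW = np.abs(W)
    if gamma is None:
        gamma = 1e-8 * absW.max() if absW.size else 0.0
    dW = cwt_map.d_coeffs
    if dW is None:
        n = W.shape[1]
        xi = np.fft.fftfreq(n) * cwt_map.grid.fs
        dW = ifft(fft(W, axis=1) * (1j * 2 * np.pi * xi)[None, :], axis=1)
    valid = absW > gamma
    omega = np.zeros_like(absW)
    np.divide(dW.imag * W.real - dW.real * W.imag, absW**2, out=omega, where=valid)
    omega /= 2.0 * np.pi
    omega[~valid] = 0.0
    return PhaseMap(omega=omega, valid_mask=valid, gamma=float(gamma))


def synchrosqueeze(
    cwt_map: CWTMap,
    phase: PhaseMap,
    freq_bins: int = 128,
    fmin: float | None = None,
    fmax: float | None = None,
) -> SWTMap:
    """Reassign CWT coefficients onto a linear frequency grid.

    Each valid coefficient with instantaneous frequency inside
    ``[fmin, fmax]`` contributes ``W * ln(2)/voices`` to the nearest bin
    (ties resolved to the lower bin); frequencies outside the span are
    discarded.
    """
    if freq_bins < 2:
        raise ValueError("freq_bins must be >= 2")
    grid = cwt_map.grid
    fmin = grid.fmin if fmin is None else fmin
    fmax = grid.fmax if fmax is None else fmax
    if not fmin < fmax:
        raise ValueError("need fmin < fmax")
    freqs = np.linspace(fmin, fmax, freq_bins)
    df = freqs[1] - freqs[0]

    weight = LOG2 / grid.voices_per_octave
    omega = phase.omega
    keep = phase.valid_mask & (omega >= fmin) & (omega <= fmax)
    # Nearest bin, exact midpoints going to the lower bin.
    idx = np.ceil((omega - fmin) / df - 0.5).astype(np.int64)
    np.clip(idx, 0, freq_bins - 1, out=idx)

    n_times = cwt_map.n_times
    out = np.zeros((freq_bins, n_times), dtype=np.complex128)
    rows, cols = np.nonzero(keep)
    np.add.at(out, (idx[rows, cols], cols), cwt_map.coeffs[rows, cols] * weight)
    return SWTMap(coeffs=out, freqs=freqs, times=cwt_map.times.copy())


def swt(
    signal: np.ndarray,
    wavelet: WaveletSpec | None = None,
    grid: ScaleGrid | None = None,
    *,
    fs: float | None = None,
    freq_bins: int = 128,
    gamma: float | None = None,
) -> SWTMap:
    """Convenience chain: CWT -> phase transform -> synchrosqueeze."""
    cmap = cwt(signal, wavelet, grid, fs=fs)
    return synchrosqueeze(cmap, phase_transform(cmap, gamma), freq_bins)


def ridge(swt_map: SWTMap) -> np.ndarray:
    """Per-column frequency of maximal magnitude (Hz)."""
    return swt_map.freqs[np.abs(swt_map.coeffs).argmax(axis=0)]


def interpolate_cwt_magnitude(cwt_map: CWTMap, freqs: np.ndarray) -> np.ndarray:
    """|CWT| interpolated column-wise onto an ascending linear frequency
    grid (used for like-for-like CWT/SWT comparisons)."""
    src = cwt_map.grid.freqs[::-1]  # ascending
    mag = np.abs(cwt_map.coeffs)[::-1]
    out = np.empty((len(freqs), cwt_map.n_times))
    for j in range(cwt_map.n_times):
        out[:, j] = np.interp(freqs, src, mag[:, j])
    return out
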