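"""Continuous wavelet transform and pairwise semblance/coherence maps.

The transform is an analytic Morlet CWT evaluated in the Fourier domain on a
logarithmic scale grid. Coherence follows the standard smoothed-cross-power
normalization (scale-dependent Gaussian smoothing in time, boxcar across
scales); without smoothing the coherence estimator degenerates to 1
everywhere, which is asserted by a guard test. Semblance is the cosine of
the raw (unsmoothed) cross-spectrum phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import fftconvolve

from .errors import ComputeError, ConfigError

log = logging.getLogger(__name__)

_MORLET_PI4 = np.pi ** -0.25


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of Fourier period to wavelet scale for the analytic Morlet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


def scale_to_freq(scales: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    return 1.0 / (morlet_fourier_factor(omega0) * np.asarray(scales, dtype=float))


def freq_to_scale(freqs: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    return 1.0 / (morlet_fourier_factor(omega0) * np.asarray(freqs, dtype=float))


def scale_grid_for_band(band_hz: tuple[float, float], *, omega0: float = 6.0,
                        voices_per_octave: int = 12,
                        margin: float = 2.0) -> np.ndarray:
    """Logarithmic scale grid spanning ``f_low / margin`` to ``f_high * margin``."""
    f_low, f_high = band_hz
    if not (0 < f_low < f_high):
        raise ConfigError(f"invalid band {band_hz}")
    s_min = float(freq_to_scale(f_high * margin, omega0))
    s_max = float(freq_to_scale(f_low / margin, omega0))
    n = int(np.ceil(voices_per_octave * np.log2(s_max / s_min))) + 1
    return s_min * 2.0 ** (np.arange(n) / voices_per_octave)


@dataclass
class WaveletDecomposition:
    """Complex CWT coefficients on a (scale x time) grid with COI bookkeeping.

    ``coi_min_freq[t]`` is the lowest equivalent Fourier frequency unaffected
    by edge effects at time index t; a grid cell (j, t) lies inside the cone
    of influence iff ``freqs[j] > coi_min_freq[t]``.
    """

    coefficients: np.ndarray
    scales: np.ndarray
    freqs: np.ndarray
    dt: float
    coi_min_freq: np.ndarray
    omega0: float = 6.0

    def __post_init__(self) -> None:
        ns, nt = self.coefficients.shape
        if self.scales.shape != (ns,) or self.freqs.shape != (ns,):
            raise ComputeError("decomposition grid dimensions inconsistent")
        if self.coi_min_freq.shape != (nt,):
            raise ComputeError("COI length must equal time length")
        if ns >= 2 and not np.all(np.diff(self.freqs) < 0):
            raise ComputeError("freqs must strictly decrease with scale")

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[1]

    def inside_coi(self) -> np.ndarray:
        """Boolean (scale x time) map: True where the cell is edge-safe."""
        return self.freqs[:, None] > self.coi_min_freq[None, :]


def cwt_morlet(signal: np.ndarray, dt: float, scales: np.ndarray, *,
               omega0: float = 6.0, normalize: bool = True) -> WaveletDecomposition:
    """Analytic Morlet CWT of a uniformly sampled signal.

    The signal is mean-removed and (optionally) variance-normalized, then
    zero-padded to the next power of two; padding is discarded before the
    coefficients are returned. The COI uses the e-folding time sqrt(2)*scale.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ComputeError("signal must be 1-D with at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ComputeError("signal contains non-finite samples")
    scales = np.asarray(scales, dtype=float)
    if np.any(scale_to_freq(scales, omega0) >= 0.5 / dt):
        raise ConfigError("scale grid reaches frequencies at or above Nyquist")

    n = x.size
    x = x - x.mean()
    if normalize:
        sd = x.std()
        if sd > 0:
            x = x / sd
    npad = 1 << int(np.ceil(np.log2(max(n, 2))))
    xf = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    pos = omega > 0

    norm_base = np.sqrt(2.0 * np.pi / dt) * _MORLET_PI4
    psi_hat = np.zeros((scales.size, npad))
    psi_hat[:, pos] = (norm_base * np.sqrt(scales)[:, None]
                       * np.exp(-0.5 * (scales[:, None] * omega[None, pos] - omega0) ** 2))
    coeffs = np.fft.ifft(xf[None, :] * psi_hat, axis=1)[:, :n]

    # distance (s) to nearest edge; scale valid when sqrt(2)*s < distance
    t_idx = np.arange(n, dtype=float)
    edge_dist = np.minimum(t_idx, n - 1 - t_idx) * dt
    with np.errstate(divide="ignore"):
        coi_min_freq = np.where(edge_dist > 0,
                                1.0 / (morlet_fourier_factor(omega0)
                                       * (edge_dist / np.sqrt(2.0))),
                                np.inf)
    return WaveletDecomposition(coeffs, scales, scale_to_freq(scales, omega0),
                                float(dt), coi_min_freq, omega0)


def cross_spectrum(wx: WaveletDecomposition, wy: WaveletDecomposition) -> np.ndarray:
    """Elementwise Wx * conj(Wy)."""
    _check_grids(wx, wy)
    return wx.coefficients * np.conj(wy.coefficients)


def smooth(values: np.ndarray, scales: np.ndarray, dt: float, *,
           decorrelation: float = 0.6) -> np.ndarray:
    """Scale-dependent time smoothing then boxcar smoothing across scales.

    Time axis: Gaussian of standard deviation ``scale / sqrt(2)`` (the modulus
    envelope of the Morlet); scale axis: boxcar spanning ``decorrelation`` in
    log2-scale units. Linear, and exactly preserves constant maps.
    """
    values = np.asarray(values)
    out = np.empty_like(values, dtype=complex if np.iscomplexobj(values) else float)
    for j, s in enumerate(scales):
        out[j] = _gauss_smooth_row(values[j], (s / np.sqrt(2.0)) / dt)
    if scales.size >= 2:
        dj = np.log2(scales[1] / scales[0])
        width = max(1, int(round(decorrelation / dj)))
        if width > 1:
            kernel = np.ones(width)
            # normalize by the actual kernel overlap so constants survive edges
            denom = np.convolve(np.ones(scales.size), kernel, mode="same")
            out = convolve1d(out.real, kernel, axis=0, mode="constant") / denom[:, None] \
                + (1j * convolve1d(out.imag, kernel, axis=0, mode="constant")
                   / denom[:, None] if np.iscomplexobj(out) else 0.0)
    return out if np.iscomplexobj(values) else out.real


def _gauss_smooth_row(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with edge replication, FFT-accelerated for wide
    kernels; matches ndimage's 'nearest' mode semantics."""
    if sigma < 1e-12:
        return x.copy()
    radius = int(4.0 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    padded = np.concatenate([np.full(radius, x[0]), x, np.full(radius, x[-1])])
    if np.iscomplexobj(x):
        return fftconvolve(padded, k, mode="same")[radius:-radius]
    return fftconvolve(padded, k, mode="same")[radius:-radius].real


def wavelet_coherence(wx: WaveletDecomposition, wy: WaveletDecomposition, *,
                      smoothed: bool = True) -> np.ndarray:
    """Magnitude-squared wavelet coherence map in [0, 1].

    ``smoothed=False`` exposes the known degeneracy (identically 1) and exists
    only so tests can document why smoothing is mandatory.
    """
    _check_grids(wx, wy)
    sinv = 1.0 / wx.scales[:, None]
    cross = sinv * cross_spectrum(wx, wy)
    px = sinv * np.abs(wx.coefficients) ** 2
    py = sinv * np.abs(wy.coefficients) ** 2
    if smoothed:
        cross = smooth(cross, wx.scales, wx.dt)
        px = smooth(px, wx.scales, wx.dt)
        py = smooth(py, wx.scales, wx.dt)
    denom = px * py
    out = np.zeros_like(px)
    good = denom > 0
    if not np.all(good):
        log.warning("wavelet_coherence: %d zero-power cells set to 0", int((~good).sum()))
    out[good] = np.abs(cross[good]) ** 2 / denom[good]
    return np.clip(out, 0.0, 1.0)


def wavelet_semblance(wx: WaveletDecomposition, wy: WaveletDecomposition, *,
                      exponent: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """cos(cross-spectrum phase) map in [-1, 1] plus a validity map.

    Cells where either transform has zero amplitude have undefined phase;
    they are returned as 0 with ``valid`` False so means can exclude them.
    Odd ``exponent`` values sharpen the index (cos^n) while keeping sign.
    """
    _check_grids(wx, wy)
    cross = cross_spectrum(wx, wy)
    amp = np.abs(cross)
    valid = amp > 0
    sem = np.zeros_like(amp)
    # cos(phase) as Re/|.| keeps sign-flip antisymmetry bit-exact
    sem[valid] = (cross.real[valid] / amp[valid]) ** exponent \
        if exponent != 1 else cross.real[valid] / amp[valid]
    return np.clip(sem, -1.0, 1.0), valid


def band_epoch_mean(values: np.ndarray, dec: WaveletDecomposition,
                    band_hz: tuple[float, float],
                    valid: np.ndarray | None = None, *,
                    mode: str = "pooled") -> tuple[float, float]:
    """Mean of a map over in-band, in-COI, valid cells.

    Returns ``(mean, valid_fraction)`` where valid_fraction is the kept share
    of in-band grid cells. ``mode='scalewise'`` averages along time first and
    then across scales; the default pools all cells equally.
    """
    f_low, f_high = band_hz
    in_band = (dec.freqs >= f_low) & (dec.freqs <= f_high)
    if not np.any(in_band):
        raise ComputeError(f"band {band_hz} does not intersect the scale grid")
    keep = dec.inside_coi()
    if valid is not None:
        keep = keep & valid
    keep = keep & in_band[:, None]
    n_band_cells = int(in_band.sum()) * dec.n_times
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ComputeError("no valid grid cells in band (COI exhausted the epoch?)")
    if mode == "pooled":
        mean = float(values[keep].sum() / n_keep)
    elif mode == "scalewise":
        rows = []
        for j in np.flatnonzero(in_band):
            k = keep[j]
            if k.any():
                rows.append(values[j, k].mean())
        mean = float(np.mean(rows))
    else:
        raise ConfigError(f"unknown mean mode {mode!r}")
    return mean, n_keep / n_band_cells


@dataclass
class PairIndexResult:
    """Semblance/coherence maps and band-mean scalars for one signal pair."""

    pair: tuple[str, str]
    band_hz: tuple[float, float]
    band_mean_semblance: float | None = None
    band_mean_coherence: float | None = None
    valid_fraction: float = 0.0
    semblance_map: np.ndarray | None = field(default=None, repr=False)
    coherence_map: np.ndarray | None = field(default=None, repr=False)
    decomposition: WaveletDecomposition | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.band_mean_semblance is not None and not -1 - 1e-9 <= self.band_mean_semblance <= 1 + 1e-9:
            raise ComputeError("band-mean semblance outside [-1, 1]")
        if self.band_mean_coherence is not None and not -1e-9 <= self.band_mean_coherence <= 1 + 1e-9:
            raise ComputeError("band-mean coherence outside [0, 1]")


def pair_indices(x: np.ndarray, y: np.ndarray, dt: float,
                 band_hz: tuple[float, float] = (0.003, 0.05), *,
                 pair: tuple[str, str] = ("x", "y"), omega0: float = 6.0,
                 voices_per_octave: int = 12, semblance_exponent: int = 1,
                 kinds: tuple[str, ...] = ("semblance", "coherence"),
                 mean_mode: str = "pooled",
                 keep_maps: bool = False) -> PairIndexResult:
    """End-to-end semblance/coherence for one pair of uniform signals."""
    if len(x) != len(y):
        raise ComputeError("pair signals must have equal length")
    scales = scale_grid_for_band(band_hz, omega0=omega0,
                                 voices_per_octave=voices_per_octave)
    wx = cwt_morlet(x, dt, scales, omega0=omega0)
    wy = cwt_morlet(y, dt, scales, omega0=omega0)
    sem_mean = coh_mean = None
    sem_map = coh_map = None
    valid_fraction = 0.0
    if "semblance" in kinds:
        sem_map, valid = wavelet_semblance(wx, wy, exponent=semblance_exponent)
        sem_mean, valid_fraction = band_epoch_mean(sem_map, wx, band_hz, valid,
                                                   mode=mean_mode)
    if "coherence" in kinds:
        coh_map = wavelet_coherence(wx, wy)
        coh_mean, vf = band_epoch_mean(coh_map, wx, band_hz, mode=mean_mode)
        valid_fraction = valid_fraction or vf
    return PairIndexResult(
        pair=pair, band_hz=band_hz,
        band_mean_semblance=sem_mean, band_mean_coherence=coh_mean,
        valid_fraction=valid_fraction,
        semblance_map=sem_map if keep_maps else None,
        coherence_map=coh_map if keep_maps else None,
        decomposition=wx if keep_maps else None)


def _check_grids(wx: WaveletDecomposition, wy: WaveletDecomposition) -> None:
    if wx.coefficients.shape != wy.coefficients.shape:
        raise ComputeError("decomposition grids differ in shape")
    if not np.allclose(wx.scales, wy.scales) or wx.dt != wy.dt:
        raise ComputeError("decomposition grids differ in scales or dt")
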