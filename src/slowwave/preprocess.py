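"""Cleaning chain: threshold/moving-SD artifact handling, interpolation
repair, discrete wavelet denoising, resampling/synchronization, and derived
haemoglobin channels.

Rule split: MABP (and other systemic channels) use the baseline-threshold
rule with linear repair; optical channels use moving-SD despiking with
cubic-spline repair followed by wavelet denoising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .data import AnalysisConfig, Recording, TimeSeriesChannel
from .errors import DataError

log = logging.getLogger(__name__)

OPTICAL_CHANNELS = ("HbO2", "HHb", "HbD", "HbT", "oxCCO", "BFI")


@dataclass
class ArtifactMask:
    """Per-sample artifact flags aligned to one channel."""

    flags: np.ndarray
    provenance: str  # threshold-rule | moving-SD | injected-truth

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def detect_threshold_artifacts(chan: TimeSeriesChannel,
                               baseline_window: tuple[float, float],
                               threshold_frac: float = 0.15, *,
                               max_artifact_s: float = 30.0) -> ArtifactMask:
    """Flag brief excursions beyond a fractional deviation from baseline.

    The baseline reference is the median of the baseline window. Excursions
    lasting ``max_artifact_s`` or longer are treated as consistent signal
    changes and left unflagged.
    """
    t0, t1 = baseline_window
    in_base = (chan.times >= t0) & (chan.times <= t1) & ~chan.mask
    if not np.any(in_base):
        raise DataError(f"channel {chan.name}: empty baseline window {baseline_window}")
    ref = float(np.median(chan.values[in_base]))
    if ref <= 0:
        raise DataError(f"channel {chan.name}: baseline reference {ref} <= 0; "
                        "relative threshold undefined")
    rel = np.abs(chan.values - ref) / ref
    candidate = (rel > threshold_frac) & ~chan.mask
    flags = np.zeros(len(chan), dtype=bool)
    for start, stop in _runs(candidate):
        dur = chan.times[stop - 1] - chan.times[start] + 1.0 / chan.native_rate
        ends_open = stop == len(chan)  # excursion persisting past the record end
        if dur < max_artifact_s and not (ends_open and dur >= max_artifact_s):
            flags[start:stop] = True
    return ArtifactMask(flags, "threshold-rule")


def repair_by_interpolation(chan: TimeSeriesChannel, mask: ArtifactMask | np.ndarray,
                            method: str = "linear") -> TimeSeriesChannel:
    """Replace flagged samples by interpolation over unflagged neighbours."""
    flags = mask.flags if isinstance(mask, ArtifactMask) else np.asarray(mask, bool)
    if flags.shape != chan.values.shape:
        raise DataError("mask length mismatch")
    if flags.all():
        raise DataError(f"channel {chan.name}: mask covers the entire channel")
    out = chan.copy()
    if not flags.any():
        return out
    good = ~flags
    if method == "linear":
        out.values[flags] = np.interp(chan.times[flags], chan.times[good],
                                      chan.values[good])
    elif method == "spline":
        if good.sum() >= 4:
            cs = CubicSpline(chan.times[good], chan.values[good])
            out.values[flags] = cs(chan.times[flags])
        else:
            out.values[flags] = np.interp(chan.times[flags], chan.times[good],
                                          chan.values[good])
    else:
        raise DataError(f"unknown repair method {method!r}")
    out.mask = out.mask & ~flags
    return out


def despike_moving_sd(chan: TimeSeriesChannel, window: int = 20,
                      k_sd: float = 3.0) -> tuple[TimeSeriesChannel, ArtifactMask]:
    """Flag samples > k_sd local SDs from the local mean, then spline-repair.

    ``window`` is in samples (centred). A locally constant channel has zero
    SD and nothing is flagged there.
    """
    if window < 5:
        raise DataError("despike window must span >= 5 samples")
    s = pd.Series(np.where(chan.mask, np.nan, chan.values))
    roll = s.rolling(window, center=True, min_periods=3)
    mu = roll.mean().to_numpy()
    sd = roll.std().to_numpy()
    with np.errstate(invalid="ignore"):
        flags = (np.abs(chan.values - mu) > k_sd * sd) & (sd > 1e-12) & ~chan.mask
    flags = np.nan_to_num(flags).astype(bool)
    mask = ArtifactMask(flags, "moving-SD")
    if flags.all():
        raise DataError(f"channel {chan.name}: despike flagged every sample")
    repaired = repair_by_interpolation(chan, mask, method="spline") if flags.any() \
        else chan.copy()
    return repaired, mask


# ---------------------------------------------------------------------------
# Discrete wavelet denoising (4-tap Daubechies, periodized)
# ---------------------------------------------------------------------------

_SQ3 = np.sqrt(3.0)
_D4_LO = np.array([1.0 + _SQ3, 3.0 + _SQ3, 3.0 - _SQ3, 1.0 - _SQ3]) / (4.0 * np.sqrt(2.0))
_D4_HI = np.array([_D4_LO[3], -_D4_LO[2], _D4_LO[1], -_D4_LO[0]])


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    idx = (np.arange(n // 2)[:, None] * 2 + np.arange(4)[None, :]) % n
    tiles = x[idx]
    return tiles @ _D4_LO, tiles @ _D4_HI


def _idwt_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * a.size
    x = np.zeros(n)
    for m in range(4):
        pos = (2 * np.arange(a.size) + m) % n
        np.add.at(x, pos, a * _D4_LO[m] + d * _D4_HI[m])
    return x


def wavelet_denoise(chan: TimeSeriesChannel, *, level: int | None = None,
                    f_low_hz: float = 0.003,
                    f_high_hz: float = 0.05) -> TimeSeriesChannel:
    """Soft universal-threshold shrinkage of above-band detail coefficients.

    Depth defaults to the smallest level whose approximation band lies below
    ``f_low_hz``, so the slow-wave trend passes through untouched. Shrinkage
    is applied only to detail levels whose passband sits entirely above
    ``f_high_hz``: high-frequency noise is suppressed while in-band power is
    preserved. The noise scale is the MAD of the finest detail level; a
    noiseless slow signal therefore gets a near-zero threshold and survives
    unchanged. Output length equals input length.
    """
    n = len(chan)
    if n < 16:
        raise DataError(f"channel {chan.name}: too short for wavelet denoising ({n})")
    fs = chan.native_rate
    if level is None:
        # approximation covers [0, fs / 2**(level+1)); push it under f_low
        level = max(1, int(np.ceil(np.log2(fs / f_low_hz))) - 1)
    npad = 1 << int(np.ceil(np.log2(n)))
    level = min(level, int(np.log2(npad)) - 2)
    x = chan.values.astype(float).copy()
    x[chan.mask] = np.interp(chan.times[chan.mask], chan.times[~chan.mask],
                             chan.values[~chan.mask]) if chan.mask.any() else x[chan.mask]
    padded = np.concatenate([x, x[::-1][: npad - n]]) if npad > n else x

    approx = padded
    details: list[np.ndarray] = []
    for _ in range(level):
        approx, d = _dwt_step(approx)
        details.append(d)
    sigma = np.median(np.abs(details[0])) / 0.6745 if details else 0.0
    lam = sigma * np.sqrt(2.0 * np.log(npad))
    shrunk = []
    for j, d in enumerate(details, start=1):
        if fs / 2.0 ** (j + 1) >= f_high_hz:  # level band entirely above f_high
            shrunk.append(np.sign(d) * np.maximum(np.abs(d) - lam, 0.0))
        else:
            shrunk.append(d)
    for d in reversed(shrunk):
        approx = _idwt_step(approx, d)
    out = chan.copy()
    out.values = approx[:n]
    out.mask = np.zeros(n, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Resampling / synchronization and derived channels
# ---------------------------------------------------------------------------

def synchronize(rec: Recording, target_rate_hz: float = 1.0) -> Recording:
    """Resample every channel onto one shared uniform time base.

    Channels above the target rate are low-pass filtered (zero-phase
    Butterworth at 0.45x the target rate) before decimation by interpolation;
    channels at or below it are linearly interpolated with a warning when
    genuinely upsampled. Channels already on the target grid pass through.
    """
    if not rec.channels:
        raise DataError("recording has no channels")
    start = max(ch.times[0] for ch in rec.channels.values())
    stop = min(ch.times[-1] for ch in rec.channels.values())
    if stop <= start:
        raise DataError("channels do not overlap in time")
    dt = 1.0 / target_rate_hz
    n = int(np.floor((stop - start) * target_rate_hz)) + 1
    grid = start + np.arange(n) * dt

    out: dict[str, TimeSeriesChannel] = {}
    for name, ch in rec.channels.items():
        if (len(ch) == n and abs(ch.native_rate - target_rate_hz) < 1e-9
                and np.max(np.abs(ch.times - grid)) < 1e-9):
            out[name] = ch.copy()
            out[name].native_rate = target_rate_hz
            continue
        good = ~ch.mask
        times, vals = ch.times[good], ch.values[good]
        if ch.native_rate > target_rate_hz * 1.05:
            wn = 0.45 * target_rate_hz / (ch.native_rate / 2.0)
            b, a = butter(4, wn)
            vals = filtfilt(b, a, vals)
        elif ch.native_rate < target_rate_hz * 0.95:
            warnings.warn(f"channel {name}: upsampling {ch.native_rate} Hz -> "
                          f"{target_rate_hz} Hz by linear interpolation", stacklevel=2)
        out[name] = TimeSeriesChannel(name, grid, np.interp(grid, times, vals),
                                      target_rate_hz, np.zeros(n, dtype=bool))
    return Recording(rec.subject_id, rec.group, out, rec.insult_onset_s,
                     rec.baseline_window_s)


def derive_channels(rec: Recording) -> Recording:
    """Add HbD = HbO2 - HHb and HbT = HbO2 + HHb (samplewise).

    Pass-through for channels already present. Requires the constituents on
    a shared time base.
    """
    out = rec.copy()
    need = [nm for nm in ("HbD", "HbT") if nm not in out.channels]
    if not need:
        return out
    if "HbO2" not in out.channels or "HHb" not in out.channels:
        raise DataError("derive_channels: HbO2 and HHb required")
    o, h = out.channels["HbO2"], out.channels["HHb"]
    if len(o) != len(h) or not np.allclose(o.times, h.times, atol=1e-9):
        raise DataError("derive_channels: HbO2 and HHb not synchronized")
    if "HbD" in need:
        out.channels["HbD"] = TimeSeriesChannel("HbD", o.times.copy(),
                                                o.values - h.values, o.native_rate,
                                                o.mask | h.mask)
    if "HbT" in need:
        out.channels["HbT"] = TimeSeriesChannel("HbT", o.times.copy(),
                                                o.values + h.values, o.native_rate,
                                                o.mask | h.mask)
    return out


def preprocess_recording(rec: Recording, cfg: AnalysisConfig) -> Recording:
    """Full cleaning chain in the documented order.

    1. MABP/systemic: threshold-rule detection + linear repair (when a
       baseline window is available).
    2. Optical channels: moving-SD despike + spline repair.
    3. Synchronize onto the target rate (anti-aliased).
    4. Wavelet-denoise optical channels (switchable to pre-sync order).
    5. Derive HbD/HbT.
    """
    work = rec.copy()

    def _denoise_optical(r: Recording) -> Recording:
        for nm in OPTICAL_CHANNELS:
            if nm in r.channels and len(r.channels[nm]) >= 16:
                r.channels[nm] = wavelet_denoise(r.channels[nm],
                                                 f_low_hz=cfg.band_hz[0],
                                                 f_high_hz=cfg.band_hz[1])
        return r

    if rec.baseline_window_s is not None and "MABP" in work.channels:
        try:
            m = detect_threshold_artifacts(work.channels["MABP"],
                                           rec.baseline_window_s,
                                           cfg.artifact_threshold_frac,
                                           max_artifact_s=cfg.max_artifact_s)
            if m.flags.any():
                work.channels["MABP"] = repair_by_interpolation(
                    work.channels["MABP"], m, method="linear")
        except DataError as exc:
            log.warning("MABP threshold pass skipped: %s", exc)
    for nm in OPTICAL_CHANNELS:
        if nm in work.channels and len(work.channels[nm]) >= cfg.despike_window:
            work.channels[nm], _ = despike_moving_sd(
                work.channels[nm], cfg.despike_window, cfg.despike_k_sd)
    if cfg.denoise and cfg.denoise_before_sync:
        work = _denoise_optical(work)
    work = synchronize(work, cfg.target_rate_hz)
    if cfg.denoise and not cfg.denoise_before_sync:
        work = _denoise_optical(work)
    return derive_channels(work)


def _runs(flags: np.ndarray):
    """Yield (start, stop) half-open index ranges of consecutive True."""
    flags = np.asarray(flags, bool)
    if not flags.any():
        return
    d = np.diff(flags.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(flags.size)
    yield from zip(starts, stops)
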