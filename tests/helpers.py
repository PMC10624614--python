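"""Shared test machinery: fast cohort runner and independent oracles."""

import numpy as np

from slowwave.data import AnalysisConfig, EpochSpec
from slowwave.indices import compute_cohort_indices, index_wide_frame
from slowwave.preprocess import preprocess_recording
from slowwave.simulate import SubjectGenSpec, generate_cohort
from slowwave.stats import log10_outcomes

FAST_COHORT_CFG = AnalysisConfig(
    epoch=EpochSpec(start_s=900.0, duration_s=2700.0),
    pair_list=(("BFI", "HbD"),),
    index_kinds=("semblance",),
    denoise=False,
)

FAST_GEN_SPEC = SubjectGenSpec(duration_s=4500.0, insult_onset_s=900.0)


def run_fast_cohort(seed, *, null_link=False, flat_severity=False,
                    n_per_group=None, gen_spec=FAST_GEN_SPEC, cfg=FAST_COHORT_CFG):
    """Generate -> preprocess -> BFI-HbD semblance -> joined outcome frame.

    Returns (merged frame with semblance/outcomes/group columns, truth table).
    """
    recs, outcomes, truth = generate_cohort(
        n_per_group, gen_spec, seed, null_link=null_link,
        flat_severity=flat_severity)
    clean = [preprocess_recording(r, cfg) for r in recs]
    wide = index_wide_frame(compute_cohort_indices(clean, cfg))
    out_frame = log10_outcomes(outcomes).drop(columns=["group"])
    merged = wide.merge(out_frame, on="subject_id")
    return merged, truth


# ---------------------------------------------------------------------------
# Independent wavelet-coherence oracle (time-domain convolution; shares no
# code with slowwave.wavelet)
# ---------------------------------------------------------------------------

def _oracle_cwt(x, dt, scales, omega0=6.0):
    """Morlet CWT by explicit time-domain convolution of sampled wavelets."""
    from scipy.signal import fftconvolve

    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    rows = []
    for s in scales:
        half = int(np.ceil(5.0 * s / dt))
        t = np.arange(-half, half + 1) * dt
        psi = (np.pi ** -0.25) * np.exp(1j * omega0 * t / s - 0.5 * (t / s) ** 2)
        psi *= dt / np.sqrt(s)
        rows.append(fftconvolve(x, np.conj(psi[::-1]), mode="same"))
    return np.array(rows)


def _oracle_smooth(m, scales, dt, decorrelation=0.6):
    from scipy.signal import fftconvolve

    sm = np.empty_like(m)
    for j, s in enumerate(scales):
        sigma = (s / np.sqrt(2.0)) / dt
        radius = int(4.0 * sigma + 0.5)
        if radius == 0:
            sm[j] = m[j]
            continue
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        padded = np.concatenate([np.full(radius, m[j, 0]), m[j],
                                 np.full(radius, m[j, -1])])
        sm[j] = fftconvolve(padded, k, mode="same")[radius:-radius]
    dj = np.log2(scales[1] / scales[0])
    width = max(1, int(round(decorrelation / dj)))
    if width > 1:
        box = np.ones(width)
        denom = np.convolve(np.ones(len(scales)), box, mode="same")
        out = np.empty_like(sm)
        for t in range(sm.shape[1]):
            out[:, t] = np.convolve(sm[:, t], box, mode="same") / denom
        sm = out
    return sm


def oracle_band_coherence(x, y, dt, band_hz, omega0=6.0, voices=12, margin=2.0):
    """Band/epoch-mean smoothed wavelet coherence, written from the standard
    formulas without touching the package implementation."""
    ff = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))
    s_min = 1.0 / (ff * band_hz[1] * margin)
    s_max = 1.0 / (ff * (band_hz[0] / margin))
    n_scales = int(np.ceil(voices * np.log2(s_max / s_min))) + 1
    scales = s_min * 2.0 ** (np.arange(n_scales) / voices)
    freqs = 1.0 / (ff * scales)

    wx = _oracle_cwt(np.asarray(x, float), dt, scales, omega0)
    wy = _oracle_cwt(np.asarray(y, float), dt, scales, omega0)
    sinv = 1.0 / scales[:, None]
    num = np.abs(_oracle_smooth(sinv * wx * np.conj(wy), scales, dt)) ** 2
    den = (_oracle_smooth(sinv * np.abs(wx) ** 2, scales, dt)
           * _oracle_smooth(sinv * np.abs(wy) ** 2, scales, dt))
    coh = np.clip(num.real / np.where(den.real > 0, den.real, np.inf), 0, 1)

    n = len(x)
    idx = np.arange(n, dtype=float)
    edge = np.minimum(idx, n - 1 - idx) * dt
    with np.errstate(divide="ignore"):
        coi_freq = np.where(edge > 0, np.sqrt(2.0) / (ff * edge), np.inf)
    keep = ((freqs[:, None] >= band_hz[0]) & (freqs[:, None] <= band_hz[1])
            & (freqs[:, None] > coi_freq[None, :]))
    return float(coh[keep].mean())
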