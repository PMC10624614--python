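"""Synthetic cohorts with known slow-wave coupling and linked outcomes.

Every channel is slow drift + band-limited stochastic oscillation + white
noise. Coupled pairs share a band-limited Gaussian process; the driven
channel receives a per-frequency constant phase offset of that process, so
the latent target semblance is exactly cos(phase_lag) across the shared
band. All randomness flows from one master seed through
``numpy.random.SeedSequence`` spawning: one child per subject, then fixed
child streams per purpose (oscillations, noise, artifacts, outcomes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .data import (CHANNEL_KINDS, GROUPS, OutcomeRecord, Recording,
                   TimeSeriesChannel)
from .errors import ConfigError

# Nodes are the latent signal identities oscillations are generated for.
# HbD/HbT are generated as latents and recombined into HbO2/HHb so that the
# preprocessing step HbD = HbO2 - HHb recovers them.
_LATENT_NODES = ("MABP", "HbD", "HbT", "oxCCO", "BFI")

_CHANNEL_BASE = {"MABP": 45.0, "HbO2": 30.0, "HHb": 20.0, "oxCCO": 0.5,
                 "BFI": 1.5e-6, "HR": 150.0, "SpO2": 97.0, "Temp": 38.5}
_CHANNEL_OSC_SD = {"MABP": 2.0, "HbD": 0.6, "HbT": 0.5, "oxCCO": 0.08,
                   "BFI": 1.2e-7}


@dataclass(frozen=True)
class CouplingSpec:
    """Shared-oscillation link between two named channels."""

    pair: tuple[str, str]
    phase_lag_rad: float
    coupling_weight: float
    shared_band_hz: tuple[float, float] = (0.003, 0.05)

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ConfigError(f"coupling pair {self.pair} must name two distinct channels")
        for nm in self.pair:
            if nm not in _LATENT_NODES:
                raise ConfigError(f"coupling channel {nm!r} not a generatable node "
                                  f"(one of {_LATENT_NODES})")
        if not (0.0 <= self.coupling_weight <= 1.0):
            raise ConfigError("coupling_weight must be in [0, 1]")
        if not (-np.pi <= self.phase_lag_rad <= np.pi):
            raise ConfigError("phase_lag_rad must be in [-pi, pi]")

    @property
    def target_semblance(self) -> float:
        return float(np.cos(self.phase_lag_rad))


@dataclass
class OutcomeLink:
    """Linear map from the target semblance to log10 outcomes, plus noise SD."""

    alpha: float = -0.75
    beta: float = 0.55
    sigma: float = 0.05
    tunel_alpha: float = -0.2
    tunel_beta: float = 1.6
    tunel_sigma: float = 0.15


@dataclass
class SubjectGenSpec:
    """Everything needed to synthesize one subject's recording."""

    group: str = "control"
    duration_s: float = 9000.0
    rates_hz: Mapping[str, float] = field(
        default_factory=lambda: {"MABP": 1.0, "HbO2": 1.0, "HHb": 1.0,
                                 "oxCCO": 1.0, "BFI": 1.0})
    couplings: Sequence[CouplingSpec] = ()
    osc_band_hz: tuple[float, float] = (0.003, 0.05)
    osc_sd: Mapping[str, float] = field(default_factory=lambda: dict(_CHANNEL_OSC_SD))
    noise_sd_frac: float = 0.05          # white noise SD as fraction of osc SD
    drift_amp_frac: float = 0.5          # drift SD as fraction of osc SD
    drift_timescale_s: float = 2000.0
    artifact_rate_per_hour: float = 0.0
    artifact_magnitude_frac: float = 0.3
    artifact_duration_s: tuple[float, float] = (2.0, 15.0)
    outcome_link: OutcomeLink = field(default_factory=OutcomeLink)
    insult_onset_s: float | None = None
    baseline_s: float = 900.0
    sinusoid_mode: bool = False          # pure-tone oscillations for analytic tests
    sinusoid_freq_hz: float = 0.01

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}")
        f_high = self.osc_band_hz[1]
        for nm, r in self.rates_hz.items():
            if nm not in CHANNEL_KINDS:
                raise ConfigError(f"unknown channel {nm!r} in rates_hz")
            if r <= 2.0 * f_high:
                raise ConfigError(f"channel {nm}: rate {r} Hz below 2*f_high "
                                  f"({2 * f_high} Hz)")
        if self.group != "control" and self.insult_onset_s is None:
            self.insult_onset_s = self.baseline_s


def band_limited_noise(n: int, dt: float, band_hz: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian process with spectral support restricted to a band."""
    f_low, f_high = band_hz
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=dt)
    keep = (f >= f_low) & (f <= f_high)
    if not np.any(keep):
        return np.zeros(n)
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def phase_shift(x: np.ndarray, phi: float) -> np.ndarray:
    """Apply a constant phase offset to every positive-frequency component."""
    spec = np.fft.rfft(x)
    spec[1:] = spec[1:] * np.exp(-1j * phi)
    return np.fft.irfft(spec, len(x))


@dataclass
class SubjectTruth:
    """Latent generator parameters retained for recovery tests."""

    subject_id: str
    group: str
    couplings: list[CouplingSpec]
    target_semblance: float        # for the first (outcome-linked) coupling
    coupling_weight: float


def generate_subject(spec: SubjectGenSpec, seed: int | np.random.SeedSequence, *,
                     subject_id: str = "S0") -> tuple[Recording, SubjectTruth]:
    """Synthesize one subject and its latent truth record."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    osc_ss, noise_ss, art_ss, _out_ss = ss.spawn(4)
    rng_osc = np.random.default_rng(osc_ss)

    master_rate = max(spec.rates_hz.values())
    n = int(round(spec.duration_s * master_rate))
    dt = 1.0 / master_rate
    t_master = np.arange(n) * dt

    driven_by: dict[str, CouplingSpec] = {}
    for c in spec.couplings:
        if c.pair[1] in driven_by:
            raise ConfigError(f"channel {c.pair[1]} driven by more than one coupling")
        driven_by[c.pair[1]] = c

    def fresh_osc() -> np.ndarray:
        if spec.sinusoid_mode:
            phase = rng_osc.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * spec.sinusoid_freq_hz * t_master + phase)
            return x / max(x.std(), 1e-12)
        return band_limited_noise(n, dt, spec.osc_band_hz, rng_osc)

    # driver nodes first (deterministic order), then driven nodes
    osc: dict[str, np.ndarray] = {}
    for node in _LATENT_NODES:
        if node not in driven_by:
            osc[node] = fresh_osc()
    for node in _LATENT_NODES:
        c = driven_by.get(node)
        if c is None:
            continue
        driver = osc[c.pair[0]]
        if spec.sinusoid_mode:
            shared = driver
        else:
            shared = band_limited_noise(n, dt, c.shared_band_hz, rng_osc) \
                if c.shared_band_hz != spec.osc_band_hz else driver
            if shared is not driver:
                # confine the shared component to the coupling band of the driver
                spec_d = np.fft.rfft(driver)
                f = np.fft.rfftfreq(n, d=dt)
                keep = (f >= c.shared_band_hz[0]) & (f <= c.shared_band_hz[1])
                spec_d[~keep] = 0.0
                shared = np.fft.irfft(spec_d, n)
                sd = shared.std()
                shared = shared / sd if sd > 0 else shared
        own = fresh_osc() if not spec.sinusoid_mode else band_limited_noise(
            n, dt, spec.osc_band_hz, rng_osc)
        w = c.coupling_weight
        osc[node] = (np.sqrt(w) * phase_shift(shared, c.phase_lag_rad)
                     + np.sqrt(1.0 - w) * own)

    # latent -> physical channels
    latent_sd = {nm: spec.osc_sd.get(nm, 1.0) for nm in _LATENT_NODES}
    phys: dict[str, np.ndarray] = {}
    for nm in ("MABP", "oxCCO", "BFI"):
        phys[nm] = _CHANNEL_BASE[nm] + latent_sd[nm] * osc[nm]
    hbd = latent_sd["HbD"] * osc["HbD"]
    hbt = latent_sd["HbT"] * osc["HbT"]
    phys["HbO2"] = _CHANNEL_BASE["HbO2"] + 0.5 * (hbt + hbd)
    phys["HHb"] = _CHANNEL_BASE["HHb"] + 0.5 * (hbt - hbd)

    rng_noise = np.random.default_rng(noise_ss)
    channels: dict[str, TimeSeriesChannel] = {}
    for nm, rate in spec.rates_hz.items():
        if nm not in phys:
            base = _CHANNEL_BASE.get(nm, 0.0)
            phys[nm] = np.full(n, base)
        n_ch = int(round(spec.duration_s * rate))
        t_ch = np.arange(n_ch) / rate
        vals = np.interp(t_ch, t_master, phys[nm])
        amp_sd = latent_sd.get(nm, latent_sd["HbT"] if nm in ("HbO2", "HHb") else 1.0)
        if spec.drift_amp_frac > 0:
            drift_band = (0.5 / spec.duration_s, 1.0 / spec.drift_timescale_s)
            drift = band_limited_noise(n_ch, 1.0 / rate, drift_band, rng_noise)
            vals = vals + spec.drift_amp_frac * amp_sd * drift
        if spec.noise_sd_frac > 0:
            vals = vals + spec.noise_sd_frac * amp_sd * rng_noise.standard_normal(n_ch)
        channels[nm] = TimeSeriesChannel(nm, t_ch, vals, rate)

    if spec.artifact_rate_per_hour > 0:
        rng_art = np.random.default_rng(art_ss)
        for nm in list(channels):
            art_seed = rng_art.integers(0, 2 ** 31)
            channels[nm], _ = inject_artifacts(
                channels[nm], spec.artifact_rate_per_hour,
                spec.artifact_magnitude_frac, spec.artifact_duration_s, int(art_seed))

    rec = Recording(subject_id, spec.group, channels,
                    insult_onset_s=spec.insult_onset_s,
                    baseline_window_s=(0.0, spec.baseline_s)
                    if (spec.insult_onset_s is None or spec.baseline_s <= spec.insult_onset_s)
                    else None)
    first = spec.couplings[0] if spec.couplings else None
    truth = SubjectTruth(
        subject_id=subject_id, group=spec.group,
        couplings=list(spec.couplings),
        target_semblance=first.target_semblance if first else 0.0,
        coupling_weight=first.coupling_weight if first else 0.0)
    return rec, truth


def inject_artifacts(chan: TimeSeriesChannel, rate_per_hour: float,
                     magnitude_frac: float, duration_s_range: tuple[float, float],
                     seed: int | np.random.SeedSequence,
                     ) -> tuple[TimeSeriesChannel, list[tuple[int, int]]]:
    """Add Poisson-placed transient offsets of +-magnitude_frac x local baseline.

    Returns the modified channel and the ground-truth list of flagged sample
    ranges ``(start_idx, stop_idx)`` (half-open).
    """
    if magnitude_frac <= 0:
        raise ConfigError("artifact_magnitude_frac must be > 0")
    rng = np.random.default_rng(seed)
    n = len(chan)
    if rate_per_hour <= 0 or n == 0:
        return chan.copy(), []
    duration_h = (chan.times[-1] - chan.times[0]) / 3600.0 if n > 1 else 0.0
    count = rng.poisson(rate_per_hour * duration_h)
    out = chan.copy()
    # local baseline: running median over ~60 s
    win = max(3, int(round(60.0 * chan.native_rate)) | 1)
    local_base = median_filter(chan.values, size=min(win, n), mode="nearest")
    positions: list[tuple[int, int]] = []
    for _ in range(count):
        start = int(rng.integers(0, n))
        dur_s = rng.uniform(*duration_s_range)
        width = max(1, int(round(dur_s * chan.native_rate)))
        stop = min(n, start + width)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.values[start:stop] += sign * magnitude_frac * np.abs(local_base[start:stop])
        positions.append((start, stop))
    return out, positions


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Severity presets: phase lag and coupling weight of the BFI-HbD (outcome)
#: coupling; lag shrinks and weight grows with severity so the target
#: semblance increases control < moderate < severe.
SEVERITY_PRESETS = {
    "control": {"phase_lag_rad": float(np.pi / 2.2), "coupling_weight": 0.45},
    "moderate": {"phase_lag_rad": float(np.pi / 3.2), "coupling_weight": 0.65},
    "severe": {"phase_lag_rad": float(np.pi / 12.0), "coupling_weight": 0.85},
}

#: Subject-to-subject jitter (SD, radians) applied to the preset phase lag.
LAG_JITTER_SD = 0.18

DEFAULT_N_PER_GROUP = {"control": 5, "moderate": 7, "severe": 7}

_AEEG_BY_GROUP = {"control": (3, 4), "moderate": (1, 3), "severe": (0, 2)}


def generate_cohort(n_per_group: Mapping[str, int] | None = None,
                    base_spec: SubjectGenSpec | None = None,
                    seed: int | np.random.SeedSequence = 0, *,
                    outcome_pair: tuple[str, str] = ("BFI", "HbD"),
                    null_link: bool = False, flat_severity: bool = False,
                    ) -> tuple[list[Recording], list[OutcomeRecord], pd.DataFrame]:
    """Generate a full cohort with severity-tiered coupling and linked outcomes.

    ``null_link`` severs the outcome link (beta = 0); ``flat_severity`` gives
    every group the control preset (for null-calibration cohorts). The truth
    table retains the latent parameters per subject.
    """
    n_per_group = dict(DEFAULT_N_PER_GROUP if n_per_group is None else n_per_group)
    total = sum(n_per_group.values())
    if total <= 0:
        raise ConfigError("empty cohort requested")
    base_spec = base_spec if base_spec is not None else SubjectGenSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(total)

    recordings: list[Recording] = []
    outcomes: list[OutcomeRecord] = []
    truth_rows: list[dict] = []
    idx = 0
    for group in GROUPS:
        for _ in range(n_per_group.get(group, 0)):
            sid = f"{group[:3]}{idx:02d}"
            sub_ss = subject_seeds[idx]
            param_ss, gen_ss, out_ss = sub_ss.spawn(3)
            rng_par = np.random.default_rng(param_ss)
            preset = SEVERITY_PRESETS["control" if flat_severity else group]
            lag = float(np.clip(preset["phase_lag_rad"]
                                + LAG_JITTER_SD * rng_par.standard_normal(),
                                0.0, np.pi))
            weight = float(np.clip(preset["coupling_weight"]
                                   + 0.05 * rng_par.standard_normal(), 0.0, 1.0))
            coupling = CouplingSpec(pair=outcome_pair, phase_lag_rad=lag,
                                    coupling_weight=weight,
                                    shared_band_hz=base_spec.osc_band_hz)
            spec = dataclasses.replace(base_spec, group=group, couplings=(coupling,))
            rec, truth = generate_subject(spec, gen_ss, subject_id=sid)
            recordings.append(rec)

            link = base_spec.outcome_link
            beta = 0.0 if null_link else link.beta
            tbeta = 0.0 if null_link else link.tunel_beta
            rng_out = np.random.default_rng(out_ss)
            ts = truth.target_semblance * truth.coupling_weight
            log_bgt = link.alpha + beta * ts + link.sigma * rng_out.standard_normal()
            log_wm = (link.alpha - 0.05) + beta * ts + link.sigma * rng_out.standard_normal()
            tunel = link.tunel_alpha + tbeta * ts + link.tunel_sigma * rng_out.standard_normal()
            lo, hi = _AEEG_BY_GROUP[group]
            aeeg = int(rng_out.integers(lo, hi + 1))
            outcomes.append(OutcomeRecord(
                subject_id=sid,
                bgt_lac_naa=float(np.clip(10.0 ** log_bgt, 0.01, 5.0)),
                wm_lac_naa=float(np.clip(10.0 ** log_wm, 0.01, 5.0)),
                tunel_log10=float(np.clip(tunel, -0.5, 2.0)),
                aeeg_score=aeeg, group=group))
            truth_rows.append({
                "subject_id": sid, "group": group,
                "phase_lag_rad": lag, "coupling_weight": weight,
                "target_semblance": truth.target_semblance,
                "linked_semblance": ts,
            })
            idx += 1
    return recordings, outcomes, pd.DataFrame(truth_rows)
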