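"""Domain types, delimited-text IO, and epoch selection.

Time is always seconds from recording start (float); no wall-clock parsing.
Invalid samples are carried as an explicit boolean mask (True = masked), not
dropped, so downstream artifact repair sees gap positions.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: Closed vocabulary of channel kinds; unknown names are rejected on read.
CHANNEL_KINDS = frozenset(
    {"MABP", "HbO2", "HHb", "HbD", "HbT", "oxCCO", "BFI", "HR", "SpO2", "Temp"}
)

#: Units per channel kind (documentation / manifest only).
CHANNEL_UNITS = {
    "MABP": "mmHg",
    "HbO2": "uM",
    "HHb": "uM",
    "HbD": "uM",
    "HbT": "uM",
    "oxCCO": "uM",
    "BFI": "cm^2/s",
    "HR": "bpm",
    "SpO2": "%",
    "Temp": "degC",
}

GROUPS = ("control", "moderate", "severe")

#: Default signal pairs for reactivity indices.
DEFAULT_PAIRS = (
    ("BFI", "HbD"),
    ("oxCCO", "HbD"),
    ("oxCCO", "HbT"),
    ("BFI", "MABP"),
    ("BFI", "HbT"),
    ("BFI", "oxCCO"),
    ("oxCCO", "MABP"),
)

TIME_COLUMN = "t_s"


@dataclass
class TimeSeriesChannel:
    """One named channel: sample times (s), values, and a validity mask.

    ``mask`` is True where the sample is masked (missing/artifact); masked
    values may be NaN. Times must be strictly increasing.
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    native_rate: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in CHANNEL_KINDS:
            raise DataError(f"unknown channel kind {self.name!r}; expected one of "
                            f"{sorted(CHANNEL_KINDS)}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError(f"channel {self.name}: times and values must be equal-length 1-D")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise DataError(f"channel {self.name}: times not strictly increasing")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError(f"channel {self.name}: mask length mismatch")
            self.mask = self.mask | ~np.isfinite(self.values)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise DataError(f"channel {self.name}: non-finite unmasked values")

    def __len__(self) -> int:
        return int(self.times.size)

    def copy(self) -> "TimeSeriesChannel":
        return TimeSeriesChannel(self.name, self.times.copy(), self.values.copy(),
                                 self.native_rate, self.mask.copy())

    def crop(self, t0: float, t1: float) -> "TimeSeriesChannel":
        """Return samples with t0 <= t < t1."""
        sel = (self.times >= t0) & (self.times < t1)
        return TimeSeriesChannel(self.name, self.times[sel], self.values[sel],
                                 self.native_rate, self.mask[sel])


@dataclass
class Recording:
    """A subject's multichannel recording plus metadata."""

    subject_id: str
    group: str
    channels: dict[str, TimeSeriesChannel]
    insult_onset_s: float | None = None
    baseline_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name, ch in self.channels.items():
            if name != ch.name:
                raise DataError(f"channel keyed {name!r} but named {ch.name!r}")
        if self.group != "control" and self.insult_onset_s is None:
            raise DataError(f"{self.subject_id}: insult group without insult_onset_s")
        if (self.insult_onset_s is not None and self.baseline_window_s is not None
                and self.baseline_window_s[1] > self.insult_onset_s):
            raise DataError(f"{self.subject_id}: baseline window overlaps insult onset")

    @property
    def epoch_origin_s(self) -> float:
        """Epoch clock origin: insult onset for insult groups, 0 for controls."""
        return 0.0 if self.group == "control" else float(self.insult_onset_s)

    def copy(self) -> "Recording":
        return Recording(self.subject_id, self.group,
                         {k: v.copy() for k, v in self.channels.items()},
                         self.insult_onset_s, self.baseline_window_s)


@dataclass(frozen=True)
class EpochSpec:
    """Analysis window: offset (s) from the group-dependent origin, and length."""

    start_s: float = 3600.0
    duration_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("epoch duration_s must be > 0")


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-subject outcome markers."""

    subject_id: str
    bgt_lac_naa: float
    wm_lac_naa: float
    tunel_log10: float
    aeeg_score: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.bgt_lac_naa < 0 or self.wm_lac_naa < 0:
            raise DataError(f"{self.subject_id}: Lac/NAA ratios must be >= 0")
        if not (0 <= int(self.aeeg_score) <= 4):
            raise DataError(f"{self.subject_id}: aEEG score must be in 0..4")


@dataclass
class AnalysisConfig:
    """Knobs for the full analysis chain; defaults follow the study design."""

    band_hz: tuple[float, float] = (0.003, 0.05)
    target_rate_hz: float = 1.0
    artifact_threshold_frac: float = 0.15
    epoch: EpochSpec = field(default_factory=EpochSpec)
    pair_list: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    lacnaa_threshold: float = 0.39
    alpha: float = 0.05
    seed: int = 0
    # engine details (see wavelet module)
    omega0: float = 6.0
    voices_per_octave: int = 12
    semblance_exponent: int = 1
    mean_mode: str = "pooled"  # or "scalewise"
    # preprocessing details
    max_artifact_s: float = 30.0
    despike_window: int = 20
    despike_k_sd: float = 3.0
    denoise: bool = True
    denoise_before_sync: bool = False
    # which index kinds to compute (coherence smoothing is the costly part)
    index_kinds: tuple[str, ...] = ("semblance", "coherence")

    def __post_init__(self) -> None:
        f_low, f_high = self.band_hz
        if not (0 < f_low < f_high):
            raise ConfigError(f"band_hz must satisfy 0 < f_low < f_high, got {self.band_hz}")
        if f_high >= self.target_rate_hz / 2:
            raise ConfigError(
                f"band top {f_high} Hz at or above Nyquist {self.target_rate_hz / 2} Hz")
        if not (0 < self.artifact_threshold_frac < 1):
            raise ConfigError("artifact_threshold_frac must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        self.pair_list = tuple((str(a), str(b)) for a, b in self.pair_list)
        for a, b in self.pair_list:
            for nm in (a, b):
                if nm not in CHANNEL_KINDS:
                    raise ConfigError(f"pair channel {nm!r} not a known channel kind")
        for kind in self.index_kinds:
            if kind not in ("semblance", "coherence"):
                raise ConfigError(f"unknown index kind {kind!r}")
        if self.mean_mode not in ("pooled", "scalewise"):
            raise ConfigError(f"unknown mean_mode {self.mean_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch"] = dataclasses.asdict(self.epoch)
        return d


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, *, subject_id: str, group: str,
                   insult_onset_s: float | None = None,
                   baseline_window_s: tuple[float, float] | None = None,
                   native_rates: Mapping[str, float] | None = None,
                   sep: str | None = None) -> Recording:
    """Read a recording from a delimited-text file.

    The file must carry a header row with a ``t_s`` time column and one or
    more channel columns named by kind. Non-numeric cells become masked
    samples; row count is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if TIME_COLUMN not in df.columns:
        raise DataError(f"{path}: missing time column {TIME_COLUMN!r}")
    times = pd.to_numeric(df[TIME_COLUMN], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise DataError(f"{path}: non-numeric entries in time column")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise DataError(f"{path}: time column not strictly increasing")
    channels: dict[str, TimeSeriesChannel] = {}
    for col in df.columns:
        if col == TIME_COLUMN:
            continue
        if col not in CHANNEL_KINDS:
            raise DataError(f"{path}: unknown channel column {col!r}; "
                            f"known kinds: {sorted(CHANNEL_KINDS)}")
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        rate = None if native_rates is None else native_rates.get(col)
        if rate is None:
            dt = np.median(np.diff(times)) if times.size >= 2 else 1.0
            rate = 1.0 / float(dt)
        channels[col] = TimeSeriesChannel(col, times, vals, float(rate), mask)
    if not channels:
        raise DataError(f"{path}: no channel columns found")
    return Recording(subject_id, group, channels, insult_onset_s, baseline_window_s)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a synchronized recording to CSV (inverse of :func:`read_recording`).

    Requires all channels to share one time base; masked samples are written
    as empty cells.
    """
    path = Path(path)
    names = sorted(rec.channels)
    base = rec.channels[names[0]].times
    for nm in names[1:]:
        ch = rec.channels[nm]
        if len(ch) != base.size or not np.allclose(ch.times, base, atol=1e-9):
            raise DataError(f"write_recording: channel {nm} not on the shared time base")
    out = pd.DataFrame({TIME_COLUMN: base})
    for nm in names:
        ch = rec.channels[nm]
        col = ch.values.astype(object)
        col[ch.mask] = None
        out[nm] = col
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Epoch selection
# ---------------------------------------------------------------------------

def select_epoch(rec: Recording, spec: EpochSpec,
                 required_channels: Iterable[str] | None = None) -> Recording:
    """Crop all channels to the analysis window.

    The window is ``[origin + start_s, origin + start_s + duration_s)`` where
    the origin is the insult onset for insult groups and the recording start
    for controls. Raises :class:`DataError` naming the first channel whose
    extent cannot cover the window.
    """
    t0 = rec.epoch_origin_s + spec.start_s
    t1 = t0 + spec.duration_s
    required = set(required_channels) if required_channels is not None else set(rec.channels)
    cropped: dict[str, TimeSeriesChannel] = {}
    for name, ch in rec.channels.items():
        if name in required and len(ch):
            half_dt = 0.5 / ch.native_rate
            if ch.times[0] > t0 + half_dt or ch.times[-1] < t1 - 1.5 / ch.native_rate:
                raise DataError(
                    f"{rec.subject_id}: channel {name} spans "
                    f"[{ch.times[0]:.1f}, {ch.times[-1]:.1f}] s, cannot cover epoch "
                    f"[{t0:.1f}, {t1:.1f}) s")
        cropped[name] = ch.crop(t0, t1)
    return Recording(rec.subject_id, rec.group, cropped,
                     rec.insult_onset_s, rec.baseline_window_s)


# ---------------------------------------------------------------------------
# Outcome tables and report output
# ---------------------------------------------------------------------------

def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "bgt_lac_naa", "wm_lac_naa", "tunel_log10", "aeeg_score"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: outcome table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(OutcomeRecord(
            subject_id=str(row.subject_id),
            bgt_lac_naa=float(row.bgt_lac_naa),
            wm_lac_naa=float(row.wm_lac_naa),
            tunel_log10=float(row.tunel_log10),
            aeeg_score=int(row.aeeg_score),
            group=str(getattr(row, "group")) if hasattr(row, "group") else None,
        ))
    return records


def outcomes_to_frame(outcomes: Sequence[OutcomeRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(o) for o in outcomes]
    return pd.DataFrame(rows)


def write_tables(report, out_dir: str | Path, *, config: AnalysisConfig | None = None,
                 seed: int | None = None) -> dict[str, Path]:
    """Write a cohort statistics report as CSV tables plus a JSON run manifest.

    ``report`` must expose ``to_frames() -> dict[str, DataFrame]`` (see
    ``stats.CohortStatsReport``). Returns the mapping table-name -> path.
    """
    frames = report.to_frames()
    if not frames or all(f.empty for f in frames.values()):
        raise DataError("write_tables: empty report; refusing to write empty files")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in frames.items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.12g")
        written[name] = p
    manifest = run_manifest(written, config=config, seed=seed)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = mpath
    return written


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_manifest(files: Mapping[str, Path], *, config: AnalysisConfig | None = None,
                 seed: int | None = None) -> dict:
    import scipy
    from . import __version__

    return {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": None if config is None else config.to_dict(),
        "files": {name: {"path": str(p), "sha256": file_digest(p)}
                  for name, p in files.items()},
    }
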