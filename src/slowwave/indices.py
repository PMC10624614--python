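"""Per-subject reactivity indices: band/epoch-mean semblance and coherence
for a configured list of channel pairs over the analysis epoch."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnalysisConfig, Recording, select_epoch
from .errors import ComputeError, DataError
from .wavelet import PairIndexResult, pair_indices

log = logging.getLogger(__name__)

#: valid_fraction below this marks the index as low-confidence in outputs.
LOW_CONFIDENCE_VALID_FRACTION = 0.5


@dataclass
class SubjectIndexTable:
    """Band-mean indices for one subject, keyed by pair label."""

    subject_id: str
    group: str
    results: dict[str, PairIndexResult] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for label, res in sorted(self.results.items()):
            rows.append({
                "subject_id": self.subject_id,
                "group": self.group,
                "pair": label,
                "semblance": res.band_mean_semblance,
                "coherence": res.band_mean_coherence,
                "valid_fraction": res.valid_fraction,
                "low_confidence": res.valid_fraction < LOW_CONFIDENCE_VALID_FRACTION,
            })
        return rows


def pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def compute_subject_indices(rec: Recording, cfg: AnalysisConfig, *,
                            keep_maps: bool = False,
                            assume_epoch: bool = False) -> SubjectIndexTable:
    """Epoch-select, transform, and reduce each configured pair to its
    band-mean indices.

    Missing channels skip the affected pair with a logged warning. Raises
    :class:`ComputeError` if no pair could be computed. ``assume_epoch``
    skips epoch selection for recordings already cropped to the window.
    """
    needed = {nm for p in cfg.pair_list for nm in p}
    present = needed & set(rec.channels)
    epoch_rec = rec if assume_epoch else select_epoch(rec, cfg.epoch,
                                                      required_channels=present)
    dt = 1.0 / cfg.target_rate_hz
    table = SubjectIndexTable(rec.subject_id, rec.group)
    for pair in cfg.pair_list:
        a, b = pair
        if a not in epoch_rec.channels or b not in epoch_rec.channels:
            log.warning("%s: pair %s skipped (missing channel)", rec.subject_id,
                        pair_label(pair))
            continue
        ca, cb = epoch_rec.channels[a], epoch_rec.channels[b]
        if len(ca) != len(cb):
            raise DataError(f"{rec.subject_id}: pair {pair_label(pair)} channels "
                            "not on a shared time base; synchronize first")
        table.results[pair_label(pair)] = pair_indices(
            ca.values, cb.values, dt, cfg.band_hz, pair=pair,
            omega0=cfg.omega0, voices_per_octave=cfg.voices_per_octave,
            semblance_exponent=cfg.semblance_exponent, kinds=cfg.index_kinds,
            mean_mode=cfg.mean_mode, keep_maps=keep_maps)
    if not table.results:
        raise ComputeError(f"{rec.subject_id}: no pair could be computed")
    return table


def compute_cohort_indices(recs: list[Recording],
                           cfg: AnalysisConfig) -> list[SubjectIndexTable]:
    """Per-subject tables in input order; per-subject failures are isolated."""
    if not recs:
        raise DataError("no recordings supplied")
    tables: list[SubjectIndexTable] = []
    failures: list[str] = []
    for rec in recs:
        try:
            tables.append(compute_subject_indices(rec, cfg))
        except (ComputeError, DataError) as exc:
            failures.append(rec.subject_id)
            log.warning("subject %s failed: %s", rec.subject_id, exc)
    if not tables:
        raise ComputeError(f"all {len(recs)} subjects failed index computation")
    return tables


def cohort_index_frame(tables: list[SubjectIndexTable]) -> pd.DataFrame:
    """Long-format cohort index table (one row per subject x pair)."""
    rows = [row for t in tables for row in t.to_rows()]
    return pd.DataFrame(rows)


def index_wide_frame(tables: list[SubjectIndexTable]) -> pd.DataFrame:
    """Wide per-subject frame: one column per (pair, kind), for statistics."""
    frame = cohort_index_frame(tables)
    wide = frame.pivot(index=["subject_id", "group"], columns="pair",
                       values=["semblance", "coherence"])
    wide.columns = [f"{pair}_{kind}" for kind, pair in wide.columns]
    return wide.reset_index()
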