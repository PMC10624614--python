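import numpy as np
import pytest

from slowwave.data import AnalysisConfig, EpochSpec, Recording, TimeSeriesChannel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_channel(name="MABP", values=None, rate=1.0, n=100, t0=0.0):
    if values is None:
        values = np.full(n, 50.0)
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / rate
    return TimeSeriesChannel(name, times, values, rate)


def make_recording(channels, subject_id="S0", group="control", **kw):
    return Recording(subject_id, group, {c.name: c for c in channels}, **kw)


@pytest.fixture
def fast_cfg():
    """Short-epoch config for pipeline tests: single pair, semblance only."""
    return AnalysisConfig(
        epoch=EpochSpec(start_s=900.0, duration_s=2700.0),
        pair_list=(("BFI", "HbD"),),
        index_kinds=("semblance",),
        denoise=False,
        seed=0,
    )


@pytest.fixture
def full_cfg():
    return AnalysisConfig(seed=0)
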