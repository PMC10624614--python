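"""Colour-map rendering of semblance/coherence time-scale maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .wavelet import PairIndexResult  # noqa: E402


def render_pair_maps(result: PairIndexResult, path: str | Path) -> Path:
    """Render semblance (-1..+1) and coherence (0..1) maps to one PNG."""
    if result.semblance_map is None and result.coherence_map is None:
        raise ValueError("result carries no maps; recompute with keep_maps=True")
    dec = result.decomposition
    n_panels = sum(m is not None for m in (result.semblance_map, result.coherence_map))
    fig, axes = plt.subplots(n_panels, 1, figsize=(8, 3 * n_panels), squeeze=False)
    row = 0
    extent = None
    if dec is not None:
        t1 = dec.n_times * dec.dt
        extent = (0.0, t1, np.log2(dec.freqs[-1]), np.log2(dec.freqs[0]))
    for name, cmap, vmin, vmax, data in (
            ("semblance", "RdBu_r", -1.0, 1.0, result.semblance_map),
            ("coherence", "viridis", 0.0, 1.0, result.coherence_map)):
        if data is None:
            continue
        ax = axes[row, 0]
        im = ax.imshow(data, aspect="auto", origin="upper", cmap=cmap,
                       vmin=vmin, vmax=vmax, extent=extent)
        ax.set_title(f"{result.pair[0]}-{result.pair[1]} {name}")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("log2 frequency (Hz)" if dec is not None else "scale index")
        fig.colorbar(im, ax=ax)
        if dec is not None:
            coi = np.log2(np.clip(dec.coi_min_freq, dec.freqs[-1], dec.freqs[0]))
            ax.plot(np.arange(dec.n_times) * dec.dt, coi, "w--", lw=1)
        row += 1
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
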