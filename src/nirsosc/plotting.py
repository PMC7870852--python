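"""Semblance map renderings (side outputs; never analysis inputs).

Maps follow the field's visual convention: diverging colour scale anchored
at −1 (antiphase, blue) / 0 (quadrature, green) / +1 (in phase, red), with
the y-axis in period seconds zoomed to the animal's oscillation period
± 50 s and a dotted line at the dominant period.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .semblance import PANEL_PAIRS, SemblanceMap, WaveletConfig, semblance_map
from .timeseries import ChromophoreTimeSeries


def plot_semblance_map(
    smap: SemblanceMap,
    dominant_frequency: float | None = None,
    ax=None,
    band_halfwidth_seconds: float = 50.0,
):
    """Render one time × period semblance field onto ``ax``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    periods = 1.0 / smap.frequency
    mesh = ax.pcolormesh(
        smap.time / 60.0,
        periods,
        smap.semblance,
        cmap="jet",
        vmin=-1.0,
        vmax=1.0,
        shading="nearest",
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("period (s)")
    ax.set_title(f"{smap.pair[0]}–{smap.pair[1]} semblance")
    if dominant_frequency is not None:
        period = 1.0 / dominant_frequency
        ax.axhline(period, color="k", linestyle=":", linewidth=1)
        ax.set_ylim(period - band_halfwidth_seconds, period + band_halfwidth_seconds)
    return mesh


def plot_semblance_panel(
    series: ChromophoreTimeSeries,
    dominant_frequency: float,
    config: WaveletConfig | None = None,
    path: str | Path | None = None,
):
    """Four-pair panel (HHb, HbO2, HbT, HbDiff vs oxCCO) for one animal."""
    if config is None:
        config = WaveletConfig()
    fig, axes = plt.subplots(2, 2, figsize=(11, 6), constrained_layout=True)
    mesh = None
    for ax, hb in zip(axes.ravel(), PANEL_PAIRS):
        smap = semblance_map(series, hb, "oxCCO", config)
        mesh = plot_semblance_map(smap, dominant_frequency, ax=ax)
    fig.colorbar(mesh, ax=axes, label="semblance (cos Δφ)", shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
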