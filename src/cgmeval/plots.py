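"""Diagnostic plots: Bland-Altman, Clarke error grid, SEG risk heatmap."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import seg
from .accuracy import bland_altman, clarke_zone
from .pairing import PairedReading


def bland_altman_plot(pairs: Sequence[PairedReading], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ref = np.array([p.reference_value for p in pairs])
    sen = np.array([p.sensor_value for p in pairs])
    bias, (lo, hi) = bland_altman(pairs)
    ax.scatter((ref + sen) / 2.0, ref - sen, s=10, alpha=0.6)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of reference and sensor (mg/dl)")
    ax.set_ylabel("reference - sensor (mg/dl)")
    ax.set_title(f"Bland-Altman: bias {bias:+.2f}, LoA {hi:+.1f}/{lo:+.1f}")
    return ax


def clarke_grid_plot(pairs: Sequence[PairedReading], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ref = np.array([p.reference_value for p in pairs])
    sen = np.array([p.sensor_value for p in pairs])
    zones = [clarke_zone(r, s) for r, s in zip(ref, sen)]
    colors = {"A": "tab:green", "B": "tab:olive", "C": "tab:orange",
              "D": "tab:red", "E": "darkred"}
    ax.scatter(ref, sen, c=[colors[z] for z in zones], s=10, alpha=0.7)
    ax.plot([0, 400], [0, 400], "k:", linewidth=0.8)
    ax.set_xlim(0, 400)
    ax.set_ylim(0, 400)
    ax.set_xlabel("reference glucose (mg/dl)")
    ax.set_ylabel("sensor glucose (mg/dl)")
    ax.set_title("Clarke error grid")
    return ax


def seg_heatmap(ax=None, n: int = 120):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lo, hi = seg.DOMAIN
    axis = np.linspace(lo, hi, n)
    rr, ss = np.meshgrid(axis, axis, indexing="ij")
    risks = seg.risk_grid(rr, ss)
    im = ax.pcolormesh(axis, axis, risks.T, cmap="RdYlGn_r", vmin=0, vmax=seg.RISK_MAX)
    ax.figure.colorbar(im, ax=ax, label="risk score")
    ax.set_xlabel("reference glucose (mg/dl)")
    ax.set_ylabel("sensor glucose (mg/dl)")
    ax.set_title("Surveillance-style risk surface (surrogate)")
    return ax
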