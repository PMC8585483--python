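"""PNG rendering of surface maps and sweep heatmaps (Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def save_mollweide_png(raster: np.ndarray, path, title: str = "", unit: str = "a.u."):
    """Write an equal-area surface map produced by ``mollweide_map``."""
    fig, ax = plt.subplots(figsize=(6, 3.2), dpi=150)
    im = ax.imshow(raster, origin="lower", cmap="viridis",
                   extent=[-2 * np.sqrt(2), 2 * np.sqrt(2), -np.sqrt(2), np.sqrt(2)])
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label=unit)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def save_sweep_heatmap_png(df: pd.DataFrame, path, value: str = "constriction_um"):
    """Heatmap of a Hertz sweep table over (tooth radius, depth)."""
    piv = df.pivot(index="depth_um", columns="r_teeth_um", values=value)
    fig, ax = plt.subplots(figsize=(4.5, 3.6), dpi=150)
    im = ax.imshow(piv.values, origin="lower", aspect="auto", cmap="magma",
                   extent=[piv.columns.min(), piv.columns.max(),
                           piv.index.min(), piv.index.max()])
    ax.set_xlabel("tooth radius (um)")
    ax.set_ylabel("indentation depth (um)")
    fig.colorbar(im, ax=ax, label=value)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
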