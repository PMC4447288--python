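"""QC rendering: coronal before/after montages and plane overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import SuvVolume
from .landmarks import TorsoPlanes


def _coronal(volume: SuvVolume) -> np.ndarray:
    y = volume.shape[1] // 2
    # display: z up, x across
    return volume.data[:, y, :].T[::-1]


def save_montage(before: SuvVolume, after: SuvVolume, path: str | Path,
                 vmax: float | None = None) -> None:
    """Coronal mid-slice before/after standardization, shared SUV scale."""
    vmax = vmax or float(np.percentile(before.data[before.data > 0], 99.5)
                         if (before.data > 0).any() else 1.0)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, vol, title in zip(axes, (before, after), ("native", "standardized")):
        ax.imshow(_coronal(vol), cmap="gray_r", vmax=vmax, aspect="auto")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_plane_overlay(volume: SuvVolume, planes: TorsoPlanes, path: str | Path) -> None:
    """Coronal mid-slice with the detected axial/sagittal planes drawn."""
    img = _coronal(volume)
    nz = volume.shape[2]
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.imshow(img, cmap="gray_r", aspect="auto")
    for z, label in ((planes.ns_z, "NS"), (planes.lv_z, "LV"),
                     (planes.bl_z, "BL"), (planes.th_z, "TH")):
        row = nz - 1 - z
        ax.axhline(row, color="red", lw=0.8)
        ax.text(1, row - 1, label, color="red", fontsize=7)
    for x, label in ((planes.ac_left_x, "AC-L"), (planes.ac_right_x, "AC-R")):
        ax.axvline(x, color="blue", lw=0.8)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
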