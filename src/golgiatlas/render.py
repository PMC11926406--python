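"""Rendering helpers for nMDP colocalization colormaps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .colocalization import NMDPResult


def save_nmdp_midplane(result: NMDPResult, path: str | Path) -> None:
    """Mid-z-plane slice of the nMDP field on a diverging colormap.

    Values are clamped to [-1, 1] for display (raw values in the field are
    kept unclamped); background (non-foreground) voxels render as gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    field = result.clamped()
    z = field.shape[0] // 2
    plane = np.ma.masked_invalid(field[z])
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("seismic").copy()
    cmap.set_bad(color="0.85")
    im = ax.imshow(plane, cmap=cmap, vmin=-1, vmax=1, origin="lower")
    fig.colorbar(im, ax=ax, label="nMDP")
    ax.set_title(f"nMDP mid-plane (Icorr={result.icorr:.2f})")
    ax.set_xlabel("x [voxel]")
    ax.set_ylabel("y [voxel]")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
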