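"""Colocalization statistics: thresholded Pearson r, nMDP maps, line profiles.

Pearson's r over Costes-thresholded signal voxels is the primary scalar
degree-of-colocalization measure.  The normalized mean deviation product
(nMDP) provides a per-voxel colocalization field over the segmented
foreground:

    nMDP(x) = (A(x) − ā)(B(x) − b̄) / ((a_max − ā)(b_max − b̄))

with means and maxima taken over the foreground, so positive values mark
voxels where both channels deviate from their means in the same direction.
Icorr is the fraction of foreground voxels with nMDP > 0 and
Inega-corr = 1 − Icorr the negatively/non-correlated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .image_io import MultiChannelImage, RoiMask, VoxelImage, whole_image_roi
from .thresholding import (
    CostesResult,
    build_histogram,
    costes_thresholds,
    foreground_mask,
    max_entropy_threshold,
    otsu_threshold,
)

__all__ = [
    "ColocMeasurement",
    "NMDPResult",
    "LineProfile",
    "ColocConfig",
    "pearson",
    "thresholded_pearson",
    "nmdp_map",
    "line_profile",
    "colocalize_pair",
]


def pearson(a_values: Sequence[float], b_values: Sequence[float]) -> float:
    """Pearson correlation Σ(a−ā)(b−b̄) / √(Σ(a−ā)² Σ(b−b̄)²)."""
    a = np.asarray(a_values, dtype=np.float64).ravel()
    b = np.asarray(b_values, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("unequal lengths")
    if a.size < 2:
        raise ValueError("need at least two samples")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


@dataclass(frozen=True)
class ColocMeasurement:
    """Thresholded voxel Pearson correlation for one channel pair of one cell."""

    cell_id: str
    label_a: str
    label_b: str
    r: float
    n_voxels: int
    thresholds: CostesResult | None = None
    voxel_policy: str = "or"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r = {self.r} outside [-1, 1]")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")

    def to_row(self) -> dict:
        ct = self.thresholds
        return {
            "cell_id": self.cell_id,
            "label_a": self.label_a,
            "label_b": self.label_b,
            "r": self.r,
            "n_voxels": self.n_voxels,
            "voxel_policy": self.voxel_policy,
            "t_a": ct.t_a if ct else np.nan,
            "t_b": ct.t_b if ct else np.nan,
            "costes_slope": ct.slope if ct else np.nan,
            "costes_intercept": ct.intercept if ct else np.nan,
            "costes_converged": ct.converged if ct else False,
        }


def thresholded_pearson(
    a: VoxelImage,
    b: VoxelImage,
    roi: RoiMask | None,
    ct: CostesResult,
    cell_id: str = "",
    voxel_policy: str = "or",
) -> ColocMeasurement:
    """Pearson r over the Costes signal set within the ROI.

    The signal set is ``A > t_a OR B > t_b`` by default (union policy: a
    voxel bright in either channel is signal, so mutually exclusive staining
    drives r down); ``voxel_policy='and'`` restricts to voxels above
    threshold in both channels.
    """
    if voxel_policy not in ("or", "and"):
        raise ValueError("voxel_policy must be 'or' or 'and'")
    above_a = a.data > ct.t_a
    above_b = b.data > ct.t_b
    signal = (above_a | above_b) if voxel_policy == "or" else (above_a & above_b)
    if roi is not None:
        signal &= roi.data
    n = int(signal.sum())
    if n < 2:
        raise ValueError("fewer than 2 signal voxels above the Costes thresholds")
    r = pearson(a.data[signal], b.data[signal])
    return ColocMeasurement(
        cell_id=cell_id,
        label_a=a.channel_label,
        label_b=b.channel_label,
        r=r,
        n_voxels=n,
        thresholds=ct,
        voxel_policy=voxel_policy,
    )


@dataclass(frozen=True)
class NMDPResult:
    """Per-voxel nMDP field with its Icorr / Inega-corr summary.

    ``nmdp`` is defined (finite) on foreground voxels only and NaN
    elsewhere.  Raw values are kept unclamped — the mathematical range can
    dip below −1 — and clamping to [−1, 1] happens only when rendering a
    colormap.
    """

    nmdp: np.ndarray
    icorr: float
    inega_corr: float
    seg_method: str
    n_foreground: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.icorr <= 1.0:
            raise ValueError("icorr must be in [0, 1]")
        if self.inega_corr != 1.0 - self.icorr:
            raise ValueError("inega_corr must equal 1 - icorr exactly")

    def clamped(self) -> np.ndarray:
        """Display copy with values clamped to [-1, 1]."""
        return np.clip(self.nmdp, -1.0, 1.0)


def nmdp_map(
    a: VoxelImage,
    b: VoxelImage,
    fg: RoiMask,
    seg_method: str = "otsu",
) -> NMDPResult:
    """nMDP field and Icorr over the segmented foreground.

    Means and maxima are computed over the foreground voxels (background
    must not dilute them), so a voxel at both channel maxima scores exactly
    1 and Icorr is the colocalized (positive-nMDP) fraction.
    """
    if a.shape != b.shape or fg.data.shape != a.shape:
        raise ValueError("shape mismatch")
    mask = fg.data
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty foreground")
    av = a.astype_float()[mask]
    bv = b.astype_float()[mask]
    a_mean, b_mean = av.mean(), bv.mean()
    a_max, b_max = av.max(), bv.max()
    if a_max == a_mean or b_max == b_mean:
        raise ValueError("constant channel on foreground: nMDP undefined")
    values = (av - a_mean) * (bv - b_mean) / ((a_max - a_mean) * (b_max - b_mean))
    nmdp = np.full(a.shape, np.nan, dtype=np.float64)
    nmdp[mask] = values
    icorr = float(np.count_nonzero(values > 0) / n)
    return NMDPResult(
        nmdp=nmdp,
        icorr=icorr,
        inega_corr=1.0 - icorr,
        seg_method=seg_method,
        n_foreground=n,
    )


@dataclass(frozen=True)
class LineProfile:
    """Per-channel normalized intensities sampled along a segment."""

    positions: np.ndarray
    intensities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)


def line_profile(
    img: MultiChannelImage,
    p0: Sequence[float],
    p1: Sequence[float],
    n_samples: int = 100,
) -> LineProfile:
    """Multi-channel intensity profile along a physical segment.

    ``p0`` and ``p1`` are (z, y, x) positions in μm; intensities are
    trilinearly interpolated at ``n_samples`` equispaced points and each
    channel is normalized to its own maximum along the profile (left as
    zeros if the channel is all-zero there).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    spacing = np.asarray(img.spacing)
    shape = np.asarray(img.channels[0].shape)
    t = np.linspace(0.0, 1.0, n_samples)
    points = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    idx = points / spacing  # voxel centers at index * spacing
    if np.any(idx < -1e-9) or np.any(idx > (shape - 1) + 1e-9):
        raise ValueError("segment exits the volume")
    coords = np.clip(idx, 0, shape - 1).T
    length = float(np.linalg.norm(p1 - p0))
    intensities: dict[str, np.ndarray] = {}
    for i, ch in enumerate(img.channels):
        vals = map_coordinates(ch.astype_float(), coords, order=1, mode="nearest")
        peak = vals.max()
        key = ch.channel_label or f"ch{i}"
        intensities[key] = vals / peak if peak > 0 else vals
    return LineProfile(positions=t * length, intensities=intensities)


@dataclass(frozen=True)
class ColocConfig:
    """Analysis choices for one pipeline run, recorded in provenance."""

    threshold_method: str = "otsu"  # otsu | maxentropy (for nMDP segmentation)
    n_bins: int = 256
    costes_below_set: str = "and"
    voxel_policy: str = "or"

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "maxentropy"):
            raise ValueError("threshold_method must be 'otsu' or 'maxentropy'")


def colocalize_pair(
    scene: MultiChannelImage,
    cfg: ColocConfig = ColocConfig(),
    roi: RoiMask | None = None,
) -> tuple[ColocMeasurement, NMDPResult]:
    """Full two-channel colocalization analysis of one cell.

    Runs Costes thresholding → thresholded Pearson r, and per-channel
    Otsu/MaxEntropy segmentation → nMDP with Icorr, over the whole-image
    ROI by default (the field of view covers the Golgi ribbon).
    """
    if len(scene) != 2:
        raise ValueError("exactly two channels required")
    a, b = scene.channels
    if roi is None:
        roi = whole_image_roi(a)
    ct = costes_thresholds(a, b, roi, below_set=cfg.costes_below_set)
    measurement = thresholded_pearson(
        a, b, roi, ct, cell_id=scene.cell_id, voxel_policy=cfg.voxel_policy
    )
    chooser = otsu_threshold if cfg.threshold_method == "otsu" else max_entropy_threshold
    fg = np.zeros(a.shape, dtype=bool)
    for ch in (a, b):
        hist = build_histogram(ch, roi, n_bins=cfg.n_bins)
        fg |= foreground_mask(ch, chooser(hist), roi)
    nmdp = nmdp_map(a, b, RoiMask(fg, "otsu/maxentropy union"), seg_method=cfg.threshold_method)
    return measurement, nmdp
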