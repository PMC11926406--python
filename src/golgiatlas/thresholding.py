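"""Segmentation thresholds: Otsu, maximum-entropy (Kapur), and Costes.

All three operate on explicit histograms or voxel populations so their
criteria can be checked against exhaustive brute-force evaluation.  Ties
between equally optimal thresholds are always broken toward the lowest
threshold, for determinism.

The Costes procedure finds the channel thresholds above which voxels are
treated as signal: fit the orthogonal (total-least-squares) regression of
channel B on channel A, then lower a candidate threshold ``t_a`` from the
maximum of A over its occupied intensity levels, with ``t_b`` slaved to the
regression line, until the Pearson correlation of the *below*-threshold
voxel set first drops to ≤ 0.  Everything above the accepted thresholds is
signal; the below set at the stop is statistically uncorrelated background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import RoiMask, VoxelImage

__all__ = [
    "Histogram",
    "CostesResult",
    "build_histogram",
    "otsu_threshold",
    "max_entropy_threshold",
    "costes_thresholds",
]


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram with explicit bin edges.

    ``levels`` gives the representative intensity of each bin: the integer
    value itself for integer-valued histograms (unit-width bins), the bin
    center for float data.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    integer_levels: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if counts.sum() < 1:
            raise ValueError("histogram must contain at least one sample")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def levels(self) -> np.ndarray:
        if self.integer_levels:
            return self.bin_edges[:-1]
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def build_histogram(img: VoxelImage, roi: RoiMask, n_bins: int = 256) -> Histogram:
    """Histogram of ROI voxels: unit bins for integer data, n_bins otherwise."""
    if roi.data.shape != img.shape:
        raise ValueError("ROI shape must match image")
    values = img.data[roi.data]
    if values.size == 0:
        raise ValueError("empty ROI")
    vmin, vmax = float(values.min()), float(values.max())
    integer = np.issubdtype(img.data.dtype, np.integer)
    if vmin == vmax:
        return Histogram(
            np.array([vmin, vmin + 1.0]),
            np.array([values.size]),
            integer_levels=integer,
            degenerate=True,
        )
    if integer:
        lo, hi = int(vmin), int(vmax)
        counts = np.bincount((values.astype(np.int64) - lo).ravel(), minlength=hi - lo + 1)
        edges = np.arange(lo, hi + 2, dtype=np.float64)
    else:
        counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    return Histogram(edges, counts, integer_levels=integer)


def _otsu_exact_integer(levels: np.ndarray, counts: np.ndarray) -> float:
    """Exact Otsu for integer levels/counts.

    The between-class variance is proportional to (S0·W1 − S1·W0)²/(W0·W1)
    with integer class counts W and intensity sums S, so candidates compare
    exactly by integer cross-multiplication — no floating-point near-ties.
    """
    lv = [int(v) for v in levels]
    ct = [int(c) for c in counts]
    W_tot, S_tot = sum(ct), sum(l * c for l, c in zip(lv, ct))
    best_i, best_num2, best_den = None, -1, 1
    W0 = S0 = 0
    for i in range(len(lv) - 1):
        W0 += ct[i]
        S0 += lv[i] * ct[i]
        W1 = W_tot - W0
        if W0 == 0 or W1 == 0:
            continue
        num = S0 * W1 - (S_tot - S0) * W0
        num2, den = num * num, W0 * W1
        if num2 * best_den > best_num2 * den:  # strict: ties keep lowest t
            best_i, best_num2, best_den = i, num2, den
    return float(lv[best_i])


def otsu_threshold(h: Histogram) -> float:
    """Threshold maximizing between-class variance ω0·ω1·(μ0−μ1)².

    Voxels with intensity strictly above the returned value are foreground.
    Lowest optimal threshold wins on ties.  Integer histograms are resolved
    in exact arithmetic; float histograms in double precision.
    """
    if h.degenerate or h.n_occupied < 2:
        raise ValueError("degenerate histogram: need at least two occupied levels")
    levels = h.levels
    if h.integer_levels and np.allclose(levels, np.round(levels)):
        return _otsu_exact_integer(np.round(levels), h.counts)
    counts = h.counts.astype(np.int64)
    total = counts.sum()
    W0 = np.cumsum(counts)[:-1]
    W1 = total - W0
    S0 = np.cumsum(counts * levels)[:-1]
    S_tot = float((counts * levels).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        num = S0 * W1 - (S_tot - S0) * W0
        criterion = num * num / (W0 * W1)
    criterion = np.where((W0 > 0) & (W1 > 0), criterion, -np.inf)
    return float(levels[int(np.argmax(criterion))])


def max_entropy_threshold(h: Histogram) -> float:
    """Kapur's maximum-entropy threshold: maximize H_bg(t) + H_fg(t).

    Each H is the Shannon entropy of the renormalized class histogram, with
    the convention 0·log 0 ≡ 0.  Lowest optimal threshold wins on ties.
    """
    if h.degenerate or h.n_occupied < 2:
        raise ValueError("degenerate histogram: need at least two occupied levels")
    levels = h.levels
    p = h.counts / h.counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P0 = np.cumsum(p)[:-1]
    S0 = np.cumsum(plogp)[:-1]
    P1 = 1.0 - P0
    S1 = plogp.sum() - S0
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(P0) - S0 / P0
        h1 = np.log(P1) - S1 / P1
    criterion = np.where((P0 > 0) & (P1 > 0), h0 + h1, -np.inf)
    return float(levels[int(np.argmax(criterion))])


def foreground_mask(img: VoxelImage, threshold: float, roi: RoiMask | None = None) -> np.ndarray:
    """Boolean mask of voxels strictly above the threshold (within the ROI)."""
    mask = img.data > threshold
    if roi is not None:
        mask &= roi.data
    return mask


# ---------------------------------------------------------------------------
# Costes automatic threshold


@dataclass(frozen=True)
class CostesResult:
    """Accepted Costes thresholds and the regression that slaved them.

    ``t_b = slope * t_a + intercept`` by construction.  ``converged`` means
    the downward scan found a threshold whose below-set correlation is ≤ 0;
    otherwise thresholds sit at the channel-A minimum and the whole ROI is
    signal.
    """

    t_a: float
    t_b: float
    slope: float
    intercept: float
    r_below_at_stop: float
    converged: bool
    below_set: str = "and"

    def __post_init__(self) -> None:
        if abs(self.t_b - (self.slope * self.t_a + self.intercept)) > 1e-9 * max(
            1.0, abs(self.t_b)
        ):
            raise ValueError("t_b must lie on the regression line")
        if self.converged and not self.r_below_at_stop <= 1e-12:
            raise ValueError("converged result requires r_below_at_stop <= 0")


def _orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of the principal axis of the (x, y) cloud."""
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxy <= 0:
        raise ValueError("negative-slope: Costes undefined for anti-correlated channels")
    slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def _prefix_pearson(
    x: np.ndarray, y: np.ndarray, ks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r of the first k elements, for each k in ``ks`` (vectorized)."""
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cyy, cxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    k = ks.astype(np.float64)
    idx = ks - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = cxx[idx] - cx[idx] ** 2 / k
        vy = cyy[idx] - cy[idx] ** 2 / k
        cov = cxy[idx] - cx[idx] * cy[idx] / k
        r = cov / np.sqrt(vx * vy)
    return r, vx, vy


def costes_thresholds(
    a: VoxelImage,
    b: VoxelImage,
    roi: RoiMask | None = None,
    below_set: str = "and",
) -> CostesResult:
    """Costes automatic bivariate threshold for a co-registered channel pair.

    The candidate ``t_a`` scans the occupied intensity levels of channel A
    from the maximum downward; ``t_b`` follows the orthogonal regression of
    B on A.  The scan stops at the largest ``t_a`` whose below-threshold
    voxel set (``A ≤ t_a AND B ≤ t_b`` by default, ``OR`` optionally) has
    Pearson r ≤ 0 with at least two distinct values per channel.  If no such
    crossing exists, thresholds are returned at the channel-A minimum with
    ``converged=False``.
    """
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if below_set not in ("and", "or"):
        raise ValueError("below_set must be 'and' or 'or'")
    mask = roi.data if roi is not None else np.ones(a.shape, dtype=bool)
    x = a.astype_float()[mask].ravel()
    y = b.astype_float()[mask].ravel()
    if x.size < 16:
        raise ValueError("need at least 16 ROI voxels for the Costes fit")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("a channel is constant on the ROI; Costes undefined")
    slope, intercept = _orthogonal_regression(x, y)

    # The below set shrinks monotonically as t_a decreases, so sort voxels
    # by the threshold at which each *enters* the below set and evaluate the
    # correlation on prefixes via cumulative sums.
    y_as_ta = (y - intercept) / slope
    t_enter = np.maximum(x, y_as_ta) if below_set == "and" else np.minimum(x, y_as_ta)
    order = np.argsort(t_enter)
    te_sorted = t_enter[order]
    xs, ys = x[order], y[order]

    candidates = np.unique(x)[::-1]  # occupied levels of A, descending
    ks = np.searchsorted(te_sorted, candidates, side="right")
    valid = ks >= 2
    r = np.full(candidates.shape, np.nan)
    if valid.any():
        rv, vx, vy = _prefix_pearson(xs, ys, ks[valid])
        r[valid] = np.where((vx > 0) & (vy > 0), rv, np.nan)

    crossing = np.flatnonzero(~np.isnan(r) & (r <= 0.0))
    for idx in crossing:  # largest t_a first; verify exactly, then accept
        k = ks[idx]
        sub_x, sub_y = xs[:k], ys[:k]
        if sub_x.min() == sub_x.max() or sub_y.min() == sub_y.max():
            continue  # fewer than 2 distinct values in a channel
        r_exact = float(np.corrcoef(sub_x, sub_y)[0, 1])
        if r_exact <= 0.0:
            t_a = float(candidates[idx])
            return CostesResult(
                t_a=t_a,
                t_b=slope * t_a + intercept,
                slope=slope,
                intercept=intercept,
                r_below_at_stop=r_exact,
                converged=True,
                below_set=below_set,
            )
    t_a = float(x.min())
    return CostesResult(
        t_a=t_a,
        t_b=slope * t_a + intercept,
        slope=slope,
        intercept=intercept,
        r_below_at_stop=float("nan"),
        converged=False,
        below_set=below_set,
    )
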