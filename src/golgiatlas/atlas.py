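"""The "Golgi atlas": embedding enzymes by localization dissimilarity.

Mean per-pair colocalization r̄ is turned into a dissimilarity d = 1 − r̄,
the symmetric enzyme × enzyme matrix is embedded in three dimensions by
metric MDS (SMACOF stress majorization, multiple seeded restarts), and the
3D configuration is projected to two dimensions with PCA so the atlas can
be drawn as a scatter plot: nearby points are enzymes with similar
sub-Golgi distributions.

d = 1 − r is bounded in [0, 2] but is not a metric (the triangle
inequality can fail), which metric MDS tolerates: it simply finds the
least-stress Euclidean configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .colocalization import ColocMeasurement

__all__ = [
    "DistanceMatrix",
    "AtlasEmbedding",
    "build_distance_matrix",
    "mds_embed",
    "pca_project",
    "make_atlas",
    "plot_atlas",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric enzyme × enzyme dissimilarities d = 1 − r̄."""

    labels: tuple[str, ...]
    d: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("dissimilarities must be >= 0")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "d", d)


def _mean_r_by_pair(measurements: Iterable[ColocMeasurement]) -> dict[frozenset, float]:
    by_pair: dict[frozenset, list[float]] = {}
    for m in measurements:
        key = frozenset((m.label_a, m.label_b)) if m.label_a != m.label_b else frozenset((m.label_a,))
        by_pair.setdefault(key, []).append(m.r)
    return {k: float(np.mean(v)) for k, v in by_pair.items()}


def build_distance_matrix(
    measurements: Sequence[ColocMeasurement],
    normalization: str = "none",
) -> DistanceMatrix:
    """d(X, Y) = 1 − r̄(X, Y), with r̄ the per-pair mean over cells.

    Both orderings of a pair contribute to the same mean.  Under
    ``normalization='self-control'`` the mean is first rescaled by the
    dual-label controls, r̄ ← r̄(X,Y)/√(r̄(X,X)·r̄(Y,Y)) capped at 1, so a
    pair cannot look less colocalized than the noise ceiling allows.
    The diagonal is always 0.
    """
    if normalization not in ("none", "self-control"):
        raise ValueError("normalization must be 'none' or 'self-control'")
    mean_r = _mean_r_by_pair(measurements)
    labels = sorted({lab for m in measurements for lab in (m.label_a, m.label_b)})
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two distinct labels")

    def get_r(x: str, y: str) -> float:
        key = frozenset((x, y)) if x != y else frozenset((x,))
        if key not in mean_r:
            raise ValueError(f"no measurement for pair ({x}, {y})")
        return mean_r[key]

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = get_r(labels[i], labels[j])
            if normalization == "self-control":
                r_ii, r_jj = get_r(labels[i], labels[i]), get_r(labels[j], labels[j])
                if r_ii <= 0 or r_jj <= 0:
                    raise ValueError("non-positive self-pair mean r under self-control mode")
                r = min(r / np.sqrt(r_ii * r_jj), 1.0)
            d[i, j] = d[j, i] = max(1.0 - r, 0.0)
    return DistanceMatrix(tuple(labels), d, normalization=normalization)


def _raw_stress(D: np.ndarray, X: np.ndarray) -> float:
    """Σ_{i<j} (d_ij − δ_ij)² between targets D and embedded distances."""
    return float(((pdist(X) - squareform(D, checks=False)) ** 2).sum())


def _smacof_single(
    D: np.ndarray,
    n_dims: int,
    rng: np.random.Generator,
    max_iter: int = 3000,
    eps: float = 1e-12,
) -> tuple[np.ndarray, float, list[float]]:
    """One SMACOF run from a random start; stress is non-increasing by construction."""
    n = D.shape[0]
    scale = D.max() if D.max() > 0 else 1.0
    X = rng.uniform(-scale, scale, size=(n, n_dims))
    stress = _raw_stress(D, X)
    history = [stress]
    for _ in range(max_iter):
        delta = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, D / delta, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n  # Guttman transform
        new_stress = _raw_stress(D, X)
        if new_stress > stress + 1e-9 * max(stress, 1.0):
            raise AssertionError("SMACOF stress increased — majorization broken")
        history.append(new_stress)
        if stress - new_stress < eps:
            stress = new_stress
            break
        stress = new_stress
    return X - X.mean(axis=0), stress, history


def mds_embed(
    D: DistanceMatrix,
    n_dims: int = 3,
    seed: int = 0,
    n_restarts: int = 8,
) -> tuple[np.ndarray, float]:
    """Metric MDS of a precomputed dissimilarity matrix via SMACOF.

    Runs ``n_restarts`` majorization descents from seeded random starts and
    keeps the lowest-stress configuration (centered).  Returns the (n, 3)
    coordinates and the final raw stress Σ_{i<j}(d_ij − δ_ij)².
    """
    if len(D.labels) < 3:
        raise ValueError("need at least 3 labels to embed")
    best_X, best_stress = None, np.inf
    for ss in np.random.SeedSequence(seed).spawn(n_restarts):
        X, stress, _ = _smacof_single(D.d, n_dims, np.random.default_rng(ss))
        if stress < best_stress:
            best_X, best_stress = X, stress
    return best_X, best_stress


def pca_project(coords3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project centered coordinates onto their top-2 principal components.

    Sign convention: each component's largest-magnitude loading is positive,
    so the projection is deterministic.  Returns (n, 2) scores and the two
    explained-variance fractions (non-increasing, summing to ≤ 1).
    """
    X = np.asarray(coords3d, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(X.shape[0] - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.maximum(eigvals[order], 0.0), eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    total = eigvals.sum()
    frac = eigvals[:2] / total if total > 0 else np.zeros(2)
    return Xc @ eigvecs[:, :2], frac


@dataclass(frozen=True)
class AtlasEmbedding:
    """3D MDS coordinates and their 2D PCA projection, with diagnostics."""

    labels: tuple[str, ...]
    coords3d: np.ndarray
    stress: float
    coords2d: np.ndarray
    explained_variance: np.ndarray
    seed: int
    distance_matrix: DistanceMatrix | None = None

    def as_dict2d(self) -> dict[str, tuple[float, float]]:
        return {lab: tuple(self.coords2d[i]) for i, lab in enumerate(self.labels)}


def make_atlas(
    measurements: Sequence[ColocMeasurement],
    seed: int = 0,
    normalization: str = "none",
) -> AtlasEmbedding:
    """Distance matrix → 3D metric MDS → 2D PCA, end to end."""
    D = build_distance_matrix(measurements, normalization=normalization)
    coords3d, stress = mds_embed(D, n_dims=3, seed=seed)
    coords2d, ev = pca_project(coords3d)
    return AtlasEmbedding(
        labels=D.labels,
        coords3d=coords3d,
        stress=stress,
        coords2d=coords2d,
        explained_variance=ev,
        seed=seed,
        distance_matrix=D,
    )


def plot_atlas(embedding: AtlasEmbedding, path: str | Path) -> None:
    """Labeled 2D scatter of the atlas (PC1 vs PC2)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    xy = embedding.coords2d
    ax.scatter(xy[:, 0], xy[:, 1], s=40, color="tab:blue")
    for i, lab in enumerate(embedding.labels):
        ax.annotate(lab, xy[i], textcoords="offset points", xytext=(5, 3))
    ev = embedding.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.0f}% var)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.0f}% var)")
    ax.set_title("Golgi atlas (MDS + PCA)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
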