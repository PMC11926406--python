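"""Seeded synthetic dual-color 3D Golgi-ribbon scenes with known ground truth.

The mammalian Golgi ribbon is modeled as a chain of ministacks placed along
a curved polyline.  Each ministack is a small polarized unit with a local
cis→trans axis (near the optical z-axis, with per-stack angular jitter).
An enzyme's density in a stack is a lateral Gaussian disc centered on the
stack multiplied by an axial Gaussian positioned at the enzyme's cis→trans
coordinate ``axial_mu``.  Two channels imaged from the same cell share every
geometry draw (same ministack centers and axes) and differ only in their
axial positions and in independent noise — so the ground-truth axial offset
between the two labels is the only systematic difference between channels.

The forward model for each channel is

    counts = Poisson(brightness * (density ⊛ PSF) + background) + N(0, read_noise_sd²)

with an anisotropic Gaussian PSF (worse axially), then clamped at zero:
the standard EM-CCD shot + read noise model.

Seeding
-------
``SceneConfig.seed`` fixes every stochastic draw in a scene.  Internally a
``numpy.random.SeedSequence(seed)`` is spawned into three independent
streams: geometry (shared by both channels), channel-0 noise, channel-1
noise.  ``render_panel`` derives each scene's seed from
``SeedSequence([base_seed, pair_index, cell_index])`` (pairs enumerated in
sorted unordered order, self-pairs included), so any single cell can be
re-rendered in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import MultiChannelImage, VoxelImage

__all__ = [
    "EnzymeProfile",
    "SceneConfig",
    "SyntheticScene",
    "default_ribbon_curve",
    "render_cell",
    "render_panel",
]


@dataclass(frozen=True)
class EnzymeProfile:
    """Ground-truth localization of one labeled enzyme along the stack axis.

    ``axial_mu`` is the mean position (μm) along the local cis→trans axis,
    ``axial_sigma`` its spread, ``brightness`` the mean photon count per
    unit of normalized density.
    """

    name: str
    axial_mu: float
    axial_sigma: float = 0.15
    brightness: float = 150.0

    def __post_init__(self) -> None:
        if self.axial_sigma <= 0:
            raise ValueError("axial_sigma must be > 0")
        if self.brightness <= 0:
            raise ValueError("brightness must be > 0")


def default_ribbon_curve(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    n_points: int = 7,
    amplitude_frac: float = 0.12,
    span_frac: float = 0.55,
) -> np.ndarray:
    """A gently S-curved polyline through the volume center, in μm (z, y, x).

    Spans ``span_frac`` of the x extent with a sinusoidal sway in y of
    ``amplitude_frac`` of the y extent, at constant mid-plane z.
    """
    nz, ny, nx = grid_shape
    dz, dy, dx = spacing
    ez, ey, ex = nz * dz, ny * dy, nx * dx
    t = np.linspace(-0.5, 0.5, n_points)
    x = ex / 2 + t * span_frac * ex
    y = ey / 2 + amplitude_frac * ey * np.sin(2 * np.pi * t)
    z = np.full(n_points, ez / 2)
    return np.column_stack([z, y, x])


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise parameters of one simulated acquisition.

    All physical scales are in μm; ``background`` and ``read_noise_sd`` are
    in camera counts.  ``seed`` fixes every stochastic draw.
    """

    grid_shape: tuple[int, int, int] = (64, 256, 256)
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1)
    n_ministacks: int = 10
    ribbon_curve: np.ndarray | None = None
    stack_radius: float = 0.5
    axis_jitter_deg: float = 12.0
    center_jitter: float = 0.15
    psf_sigma: tuple[float, float] = (0.3, 0.1)
    background: float = 4.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stack_radius", "center_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stack_radius <= 0:
            raise ValueError("stack_radius must be > 0")
        if any(s <= 0 for s in self.spacing) or any(s <= 0 for s in self.psf_sigma):
            raise ValueError("spacing and psf_sigma must be positive")
        if self.n_ministacks < 1:
            raise ValueError("need at least one ministack")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def curve(self) -> np.ndarray:
        if self.ribbon_curve is not None:
            return np.asarray(self.ribbon_curve, dtype=float)
        return default_ribbon_curve(self.grid_shape, self.spacing)


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered cell plus the ground truth behind it."""

    image: MultiChannelImage
    truth: tuple[EnzymeProfile, ...]
    pair_offset: float
    seed: int
    pair_label: str = ""


def _polyline_points(curve: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc length along a polyline (rows = (z, y, x) μm)."""
    seg = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    if total == 0:
        return np.repeat(curve[:1], n, axis=0)
    targets = np.linspace(0, total, n + 2)[1:-1]  # keep away from the ends
    pts = np.empty((n, 3))
    for k, t in enumerate(targets):
        i = min(np.searchsorted(s, t, side="right") - 1, len(seg) - 1)
        frac = (t - s[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        pts[k] = curve[i] + frac * seg[i]
    return pts


def _jittered_axes(rng: np.random.Generator, n: int, jitter_deg: float) -> np.ndarray:
    """Unit vectors near +z, tilted by up to ``jitter_deg`` at random azimuth."""
    theta = np.deg2rad(jitter_deg) * rng.random(n)
    phi = 2 * np.pi * rng.random(n)
    return np.column_stack(
        [np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
    )


def _splat_blob(
    density: np.ndarray,
    center: np.ndarray,
    axis: np.ndarray,
    sigma_axial: float,
    sigma_lateral: float,
    spacing: tuple[float, float, float],
) -> None:
    """Add one anisotropic Gaussian blob to ``density`` in place.

    The blob has std ``sigma_axial`` along ``axis`` and ``sigma_lateral``
    perpendicular to it, and is evaluated only on a ±4σ crop for speed.
    """
    sp = np.asarray(spacing)
    reach = 4.0 * max(sigma_axial, sigma_lateral)
    lo = np.maximum(np.floor((center - reach) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center + reach) / sp).astype(int) + 1, density.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *(np.arange(lo[i], hi[i]) * sp[i] - center[i] for i in range(3)),
        indexing="ij",
        sparse=True,
    )
    t = sum(g * a for g, a in zip(grids, axis))  # axial component
    sq = sum(g * g for g in grids)
    r2 = np.maximum(sq - t * t, 0.0)  # lateral distance²
    blob = np.exp(-t * t / (2 * sigma_axial**2) - r2 / (2 * sigma_lateral**2))
    density[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += blob


def _noiseless_channel(
    cfg: SceneConfig,
    enzyme: EnzymeProfile,
    centers: np.ndarray,
    axes: np.ndarray,
) -> np.ndarray:
    density = np.zeros(cfg.grid_shape, dtype=np.float64)
    for center, axis in zip(centers, axes):
        blob_center = center + enzyme.axial_mu * axis
        _splat_blob(density, blob_center, axis, enzyme.axial_sigma, cfg.stack_radius, cfg.spacing)
    sz, sxy = cfg.psf_sigma
    dz, dy, dx = cfg.spacing
    return gaussian_filter(density, sigma=(sz / dz, sxy / dy, sxy / dx), mode="constant")


def _check_border_mass(cfg: SceneConfig, density: np.ndarray) -> None:
    """Reject grids too small to contain the ribbon plus a 3·PSF margin."""
    sz, sxy = cfg.psf_sigma
    dz, dy, dx = cfg.spacing
    margins = [
        max(1, int(np.ceil(3 * sz / dz))),
        max(1, int(np.ceil(3 * sxy / dy))),
        max(1, int(np.ceil(3 * sxy / dx))),
    ]
    total = density.sum()
    if total == 0:
        raise ValueError("ribbon density fell entirely outside the grid")
    interior = density[margins[0] : -margins[0], margins[1] : -margins[1], margins[2] : -margins[2]]
    if interior.size == 0 or (total - interior.sum()) / total > 0.01:
        raise ValueError(
            "grid too small: more than 1% of ribbon density lies within the 3·PSF border margin"
        )


def render_cell(
    cfg: SceneConfig,
    enzymes: tuple[EnzymeProfile, EnzymeProfile],
    cell_id: str = "cell0",
) -> SyntheticScene:
    """Render one dual-channel cell; deterministic given ``(cfg, enzymes)``.

    Both channels share the same ministack geometry (same cell) and differ
    only in axial position, brightness and independent noise realizations.
    """
    if len(enzymes) != 2:
        raise ValueError("exactly two enzyme profiles required")
    geom_ss, *noise_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    geom_rng = np.random.default_rng(geom_ss)

    centers = _polyline_points(cfg.curve(), cfg.n_ministacks)
    if cfg.center_jitter > 0:
        centers = centers + geom_rng.normal(0.0, cfg.center_jitter, size=centers.shape)
    axes = _jittered_axes(geom_rng, cfg.n_ministacks, cfg.axis_jitter_deg)

    channels = []
    total_density = np.zeros(cfg.grid_shape)
    for enzyme, ss in zip(enzymes, noise_ss):
        blurred = _noiseless_channel(cfg, enzyme, centers, axes)
        total_density += blurred
        signal = enzyme.brightness * blurred + cfg.background
        rng = np.random.default_rng(ss)
        if cfg.shot_noise:
            counts = rng.poisson(signal).astype(np.float64)
        else:
            counts = signal
        if cfg.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, cfg.read_noise_sd, size=counts.shape)
        channels.append(
            VoxelImage(
                np.maximum(counts, 0.0).astype(np.float32),
                cfg.spacing,
                channel_label=enzyme.name,
            )
        )
    _check_border_mass(cfg, total_density)
    return SyntheticScene(
        image=MultiChannelImage(tuple(channels), cell_id=cell_id),
        truth=tuple(enzymes),
        pair_offset=abs(enzymes[0].axial_mu - enzymes[1].axial_mu),
        seed=cfg.seed,
        pair_label=f"{enzymes[0].name}~{enzymes[1].name}",
    )


def derive_seed(base_seed: int, pair_index: int, cell_index: int) -> int:
    """The documented per-scene seed scheme used by :func:`render_panel`."""
    ss = np.random.SeedSequence([base_seed, pair_index, cell_index])
    return int(ss.generate_state(1)[0] % (2**31))


def render_panel(
    cfg: SceneConfig,
    enzymes: list[EnzymeProfile],
    n_cells: int,
    base_seed: int,
) -> list[SyntheticScene]:
    """Render every unordered enzyme pair, including self-pairs, n_cells each.

    Self-pairs (X, X) emulate the dual-label control: the same enzyme
    profile imaged in both channels with independent noise, so any r < 1
    reflects noise alone.
    """
    if len(enzymes) < 2:
        raise ValueError("need at least two enzymes")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    scenes = []
    pairs = list(itertools.combinations_with_replacement(range(len(enzymes)), 2))
    for pair_index, (i, j) in enumerate(pairs):
        for cell in range(n_cells):
            seed = derive_seed(base_seed, pair_index, cell)
            scene_cfg = replace(cfg, seed=seed)
            scene = render_cell(
                scene_cfg,
                (enzymes[i], enzymes[j]),
                cell_id=f"{enzymes[i].name}~{enzymes[j].name}:cell{cell}",
            )
            scenes.append(scene)
    return scenes
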