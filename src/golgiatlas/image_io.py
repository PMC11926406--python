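"""Reading, writing and basic containers for multi-channel 3D voxel data.

Volumes are held in (z, y, x) axis order — TIFF pages are z-planes — with
physical voxel spacing ``(dz, dy, dx)`` in micrometres.  Voxel coordinates
are 0-based voxel centers, so the physical position of index ``i`` along an
axis is ``i * spacing``.
"""

from __future__ import annotations

import dataclasses
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelImage",
    "MultiChannelImage",
    "RoiMask",
    "read_volume",
    "write_volume",
    "write_results_table",
    "whole_image_roi",
]


@dataclass(frozen=True)
class VoxelImage:
    """One channel's 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of non-negative finite intensities, axis order (z, y, x).
        Integer data is kept at its native dtype so that file round-trips
        are bit exact; float data is converted to 32-bit float.
    spacing:
        Voxel size ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel_label:
        Free-text channel name (e.g. the enzyme or fluorophore).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={arr.ndim}")
        if any(s < 1 for s in arr.shape):
            raise ValueError("grid must have at least 1 voxel along every axis")
        if np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32, copy=False)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"unsupported dtype {arr.dtype}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_float(self) -> np.ndarray:
        """Intensities as float64, for numeric work."""
        return self.data.astype(np.float64, copy=False)


@dataclass(frozen=True)
class MultiChannelImage:
    """An ordered set of co-registered channels from one cell."""

    channels: tuple[VoxelImage, ...]
    cell_id: str = ""

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        if not channels:
            raise ValueError("at least one channel required")
        shape, spacing = channels[0].shape, channels[0].spacing
        for ch in channels[1:]:
            if ch.shape != shape:
                raise ValueError(f"channel shapes differ: {ch.shape} vs {shape}")
            if not np.allclose(ch.spacing, spacing, rtol=0, atol=1e-9):
                raise ValueError("channel spacings differ")
        object.__setattr__(self, "channels", channels)

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, i: int) -> VoxelImage:
        return self.channels[i]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.channels[0].spacing


@dataclass(frozen=True)
class RoiMask:
    """Boolean 3D gate selecting which voxels enter an analysis."""

    data: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        object.__setattr__(self, "data", arr.astype(bool, copy=False))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def whole_image_roi(img: VoxelImage) -> RoiMask:
    """ROI covering the entire volume (e.g. the whole Golgi ribbon field)."""
    return RoiMask(np.ones(img.shape, dtype=bool), description="whole image")


# ---------------------------------------------------------------------------
# TIFF I/O

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _spacing_from_ome(xml_text: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    for pixels in root.iter(f"{_OME_NS}Pixels"):
        attrs = pixels.attrib
        try:
            return (
                float(attrs["PhysicalSizeZ"]),
                float(attrs["PhysicalSizeY"]),
                float(attrs["PhysicalSizeX"]),
            )
        except KeyError:
            continue
    return None


def _spacing_from_imagej(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tf.imagej_metadata or {}
    if "spacing" not in meta:
        return None
    dz = float(meta["spacing"])
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    return (dz, float(dy), float(dx))


def read_volume(
    path: str | Path,
    channel_index: int = 0,
    spacing: tuple[float, float, float] | None = None,
) -> VoxelImage:
    """Load one channel of a TIFF / OME-TIFF z-stack as a :class:`VoxelImage`.

    Spacing is taken from OME-XML ``PhysicalSize*`` attributes or ImageJ
    metadata; the ``spacing`` argument overrides both.  If no spacing is
    available anywhere, an explicit error is raised — never a silent default.

    Integer pixel data is preserved bit-exactly; float data becomes float32.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes.upper()
        file_spacing = None
        if tf.ome_metadata:
            file_spacing = _spacing_from_ome(tf.ome_metadata)
        if file_spacing is None:
            file_spacing = _spacing_from_imagej(tf)

    # Normalize to (C, Z, Y, X), inserting singleton axes as needed.  Plain
    # multi-page TIFFs label the page axis 'Q' or 'I'; treat it as z.
    if "Z" not in axes:
        for generic in "QI":
            if generic in axes:
                axes = axes.replace(generic, "Z", 1)
                break
    for missing in "CZ":
        if missing not in axes:
            arr = np.expand_dims(arr, 0)
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    extra = [i for i in range(arr.ndim) if i not in order]
    if any(arr.shape[i] != 1 for i in extra):
        raise ValueError(f"cannot interpret TIFF axes {axes!r} as a CZYX stack")
    arr = np.squeeze(np.transpose(arr, order + extra), axis=tuple(range(4, arr.ndim)))

    n_channels = arr.shape[0]
    if not 0 <= channel_index < n_channels:
        raise IndexError(f"channel_index {channel_index} out of range for {n_channels} channel(s)")
    use_spacing = spacing if spacing is not None else file_spacing
    if use_spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in file metadata; pass spacing=(dz, dy, dx) explicitly"
        )
    return VoxelImage(arr[channel_index], tuple(use_spacing), channel_label=f"ch{channel_index}")


def write_volume(
    path: str | Path,
    image: MultiChannelImage | VoxelImage,
) -> None:
    """Write channels as an OME-TIFF stack (axes CZYX) with voxel-size metadata."""
    if isinstance(image, VoxelImage):
        image = MultiChannelImage((image,))
    dz, dy, dx = image.spacing
    stack = np.stack([ch.data for ch in image.channels])
    tifffile.imwrite(
        Path(path),
        stack,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# Tabular results


def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return rec.to_row() if hasattr(rec, "to_row") else dataclasses.asdict(rec)
    if isinstance(rec, Mapping):
        return dict(rec)
    raise TypeError(f"cannot tabulate record of type {type(rec).__name__}")


def write_results_table(
    rows: Sequence,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write measurement records to CSV with a deterministic column order.

    Column order follows the first record's field order (or ``columns``).
    Floats are written at full repr precision so values round-trip to
    better than 1e-12.  An empty record list yields a header-only CSV when
    ``columns`` is given, otherwise an empty file with no header row is
    avoided by writing the empty frame's (empty) header.
    """
    dicts = [_record_to_dict(r) for r in rows]
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    df = pd.DataFrame(dicts, columns=list(columns))
    df.to_csv(Path(path), index=False, encoding="utf-8")
    return df
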