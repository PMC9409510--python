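"""Image containers, NIfTI I/O, resampling, discretisation and difference images.

All stages of the pipeline share the two light-weight containers defined here:
:class:`ImageVolume` (a 3-D scalar grid with physical voxel spacing and frame
metadata) and :class:`VOIMask` (a binary tumor segmentation on the same grid).
Preprocessing follows common PET radiomics practice: resampling to an isotropic
2 mm grid with tri-linear interpolation of both image and mask, and fixed-bin-width
discretisation of SUV values (0.25 SUV bins anchored at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError, GeometryError

__all__ = [
    "ImageVolume",
    "VOIMask",
    "DiscretizationSettings",
    "ResampleSettings",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample",
    "discretize",
    "difference_image",
    "crop_to_mask",
]


@dataclass
class ImageVolume:
    """3-D scalar image with spacing in mm and acquisition metadata.

    ``units`` is either ``"SUV"`` or ``"kBq_per_ml"``; ``replicate`` is a
    replicate index or the string ``"reference"`` for the long acquisition.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "SUV"
    duration: float | None = None
    replicate: int | str | None = None
    protocol: str | None = None
    tumor_label: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise GeometryError(f"expected a 3-D grid, got ndim={self.grid.ndim}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class VOIMask:
    """Binary volume of interest on the same grid as its paired image."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    tumor_label: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise GeometryError(f"expected a 3-D mask, got ndim={self.grid.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not self.grid.any():
            raise DegenerateROIError("mask has no foreground voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class DiscretizationSettings:
    """Fixed-bin-width discretisation: level(v) = floor((v - origin)/width) + 1.

    Bins are half-open, ``[origin + k*width, origin + (k+1)*width)``, and the
    level is clamped at 1 so values below the origin land in the first bin.
    """

    bin_width: float = 0.25
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass(frozen=True)
class ResampleSettings:
    target_voxel_mm: float = 2.0
    mask_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.target_voxel_mm <= 0:
            raise ValueError("target_voxel_mm must be > 0")
        if not (0.0 < self.mask_threshold < 1.0):
            raise ValueError("mask_threshold must lie in (0, 1)")


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.grid, dtype=np.float64), _affine(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, **meta) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(grid=np.asarray(img.dataobj, dtype=np.float64), spacing=spacing, **meta)


def write_mask(mask: VOIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path, tumor_label: str | None = None) -> VOIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VOIMask(grid=np.asarray(img.dataobj) > 0.5, spacing=spacing, tumor_label=tumor_label)


def _check_geometry(a, b) -> None:
    if a.grid.shape != b.grid.shape:
        raise GeometryError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def _resample_grid(grid: np.ndarray, spacing: Sequence[float], target: float) -> np.ndarray:
    """Tri-linear resampling onto an isotropic grid, voxel-0 centers aligned."""
    shape = grid.shape
    new_shape = tuple(max(1, int(round(n * s / target))) for n, s in zip(shape, spacing))
    axes = [np.arange(m) * target / s for m, s in zip(new_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(grid, dtype=np.float64), coords, order=1, mode="nearest"
    )


def resample(
    volume: ImageVolume, mask: VOIMask, settings: ResampleSettings | None = None
) -> tuple[ImageVolume, VOIMask]:
    """Resample image and VOI to an isotropic grid with tri-linear interpolation.

    The binary mask is interpolated as a real-valued field and re-binarised at
    ``mask_threshold`` (fractional occupancy >= threshold keeps the voxel).
    """
    settings = settings or ResampleSettings()
    _check_geometry(volume, mask)
    t = settings.target_voxel_mm
    new_grid = _resample_grid(volume.grid, volume.spacing, t)
    mask_field = _resample_grid(mask.grid.astype(np.float64), mask.spacing, t)
    new_mask = mask_field >= settings.mask_threshold
    if not new_mask.any():
        raise DegenerateROIError("mask empty after resampling")
    vol = replace(volume, grid=new_grid, spacing=(t, t, t))
    return vol, VOIMask(grid=new_mask, spacing=(t, t, t), tumor_label=mask.tumor_label)


def discretize(
    values: np.ndarray, settings: DiscretizationSettings | None = None
) -> tuple[np.ndarray, int]:
    """Map intensities to integer grey levels; returns (levels, level count)."""
    settings = settings or DiscretizationSettings()
    values = np.asarray(values)
    if values.size == 0:
        raise DegenerateROIError("cannot discretize an empty ROI")
    levels = np.floor((values - settings.origin) / settings.bin_width).astype(np.int64) + 1
    levels = np.maximum(levels, 1)
    return levels, int(levels.max())


def difference_image(frame_a: ImageVolume, frame_b: ImageVolume) -> ImageVolume:
    """Voxelwise a - b of two statistically equivalent replicate frames."""
    _check_geometry(frame_a, frame_b)
    return replace(frame_a, grid=frame_a.grid - frame_b.grid, replicate=None)


def crop_to_mask(
    volume: ImageVolume, mask: VOIMask, margin_mm: float = 8.0
) -> tuple[ImageVolume, VOIMask]:
    """Crop both image and mask to the mask bounding box plus a physical margin.

    The margin keeps enough context for spherical-peak neighborhoods after the
    crop; cropping before resampling keeps texture computation small.
    """
    _check_geometry(volume, mask)
    idx = np.nonzero(mask.grid)
    slices = []
    for ax in range(3):
        pad = int(np.ceil(margin_mm / volume.spacing[ax]))
        lo = max(0, int(idx[ax].min()) - pad)
        hi = min(mask.grid.shape[ax], int(idx[ax].max()) + 1 + pad)
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    vol = replace(volume, grid=volume.grid[slices])
    return vol, VOIMask(grid=mask.grid[slices], spacing=mask.spacing, tumor_label=mask.tumor_label)
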