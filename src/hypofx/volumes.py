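"""Voxel dose grids, binary structure masks, and structure-set algebra.

All volumes live on one shared grid geometry: an (nx, ny, nz) array with
per-axis spacing in mm and a physical origin at the center of voxel
(0, 0, 0). The voxel-center convention applies throughout — a voxel
belongs to a structure iff its center does, and all distances are true
Euclidean distances in mm between voxel centers (anisotropic spacing is
honoured).

Margin expansion and surface cropping are built on exact Euclidean
distance transforms (:func:`scipy.ndimage.distance_transform_edt` with
physical sampling), which is the standard way treatment-planning margins
are rasterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "StructureMask",
    "StructureSet",
    "expand_mask",
    "subtract_mask",
    "union_mask",
    "intersect_mask",
    "exterior_distance",
    "crop_from_surface",
    "mask_volume",
    "write_dose_nifti",
    "read_dose_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of a plan: array shape, spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) != s or s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape!r}")
        if len(self.spacing) != 3 or any(not s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths (mm), got {self.spacing!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates (mm) along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i], dtype=float)
            for i in range(3)
        )


@dataclass(frozen=True)
class DoseGrid:
    """3D scalar field of absorbed (RBE-weighted) dose in GyE."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"dose array shape {self.values.shape} != grid shape {self.geometry.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class StructureMask:
    """Named binary occupancy volume congruent to a DoseGrid."""

    name: str
    occupancy: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.occupancy.dtype != bool:
            object.__setattr__(self, "occupancy", self.occupancy.astype(bool))
        if self.occupancy.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"mask {self.name!r} shape {self.occupancy.shape} != grid shape {self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cc(self) -> float:
        return mask_volume(self)


class StructureSet:
    """Masks keyed by canonical structure name, all on one geometry."""

    def __init__(self, geometry: GridGeometry, masks: Mapping[str, StructureMask] | None = None):
        self.geometry = geometry
        self._masks: dict[str, StructureMask] = {}
        if masks:
            for name, m in masks.items():
                self.add(m if m.name == name else StructureMask(name, m.occupancy, m.geometry))

    def add(self, mask: StructureMask) -> None:
        if mask.geometry != self.geometry:
            raise ValueError(f"mask {mask.name!r} geometry differs from the structure set's")
        if mask.name in self._masks:
            raise ValueError(f"duplicate structure name {mask.name!r}")
        self._masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def names(self) -> list[str]:
        return list(self._masks)

    def get(self, name: str) -> StructureMask | None:
        return self._masks.get(name)


# ---------------------------------------------------------------------------
# Mask algebra
# ---------------------------------------------------------------------------

def _check_congruent(a: StructureMask, b: StructureMask) -> None:
    if a.geometry != b.geometry:
        raise ValueError(
            f"masks {a.name!r} and {b.name!r} are not congruent: "
            f"{a.geometry} vs {b.geometry}"
        )


def expand_mask(m: StructureMask, margin_mm: float, name: str | None = None) -> StructureMask:
    """Isotropic margin expansion: all voxels whose center lies within
    Euclidean distance ``margin_mm`` (inclusive) of any voxel of ``m``.

    The result always contains ``m``; expansion is clipped at the array
    bounds. Distances are physical (mm), so anisotropic spacing is exact.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0 mm, got {margin_mm}")
    out_name = name or m.name
    if margin_mm == 0 or not m.occupancy.any():
        return StructureMask(out_name, m.occupancy.copy(), m.geometry)
    # distance from each voxel center to the nearest center inside m
    dist = ndimage.distance_transform_edt(~m.occupancy, sampling=m.geometry.spacing)
    # tolerate float rounding at the inclusive boundary
    grown = dist <= margin_mm * (1 + 1e-12)
    return StructureMask(out_name, grown, m.geometry)


def subtract_mask(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Voxelwise a AND NOT b."""
    _check_congruent(a, b)
    return StructureMask(name or a.name, a.occupancy & ~b.occupancy, a.geometry)


def union_mask(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Voxelwise a OR b."""
    _check_congruent(a, b)
    return StructureMask(name or a.name, a.occupancy | b.occupancy, a.geometry)


def intersect_mask(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Voxelwise a AND b."""
    _check_congruent(a, b)
    return StructureMask(name or a.name, a.occupancy & b.occupancy, a.geometry)


def exterior_distance(body: StructureMask) -> np.ndarray:
    """Distance (mm) from each voxel center to the nearest voxel center
    outside ``body``; zero outside the body."""
    return ndimage.distance_transform_edt(body.occupancy, sampling=body.geometry.spacing)


def crop_from_surface(
    m: StructureMask, body: StructureMask, depth_mm: float, name: str | None = None
) -> StructureMask:
    """Retain only voxels of ``m`` that lie inside ``body`` at Euclidean
    distance >= ``depth_mm`` from the body's exterior.

    depth 0 reduces to ``m AND body``; a mask already deeper than
    ``depth_mm`` everywhere is returned unchanged.
    """
    if depth_mm < 0:
        raise ValueError(f"depth must be >= 0 mm, got {depth_mm}")
    _check_congruent(m, body)
    dist = exterior_distance(body)
    keep = m.occupancy & body.occupancy & (dist >= depth_mm * (1 - 1e-12))
    return StructureMask(name or m.name, keep, m.geometry)


def mask_volume(m: StructureMask) -> float:
    """Structure volume in cc: voxel count times physical voxel volume."""
    return m.voxel_count * m.geometry.voxel_volume_cc


# ---------------------------------------------------------------------------
# NIfTI I/O (one file per volume; masks stored as uint8 0/1)
# ---------------------------------------------------------------------------

def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.spacing) + [1.0]).astype(float)
    aff[:3, 3] = geometry.origin
    return aff


def _geometry_from_nifti(img) -> GridGeometry:
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return GridGeometry(shape=tuple(int(s) for s in img.shape[:3]), spacing=spacing, origin=origin)


def write_dose_nifti(grid: DoseGrid, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), _affine(grid.geometry))
    nib.save(img, str(path))


def read_dose_nifti(path: str | Path) -> DoseGrid:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    return DoseGrid(values=values, geometry=_geometry_from_nifti(img))


def write_mask_nifti(mask: StructureMask, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), _affine(mask.geometry))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path, name: str) -> StructureMask:
    import nibabel as nib

    img = nib.load(str(path))
    occ = np.asarray(img.dataobj) > 0
    return StructureMask(name=name, occupancy=occ, geometry=_geometry_from_nifti(img))
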