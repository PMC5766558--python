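"""Core grid containers and file IO.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)``.  ``spacing`` and ``origin`` tuples follow
  the same axis order (millimetres).
* Grids are node-aligned: voxel ``(i, j, k)`` sits at physical position
  ``origin + (i, j, k) * spacing``.
* Label legend, fixed project-wide::

      0 = background (outside the nodule)
      1 = vessel
      2 = solid core
      3 = ground-glass

SimpleITK stores spacing/origin in ``(x, y, z)`` order; the conversion happens
only inside :func:`read_volume` / :func:`write_volume`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

BACKGROUND = 0
VESSEL = 1
CORE = 2
GROUND_GLASS = 3

#: Legend mapping label integers to class names.
LEGEND = {
    BACKGROUND: "background",
    VESSEL: "vessel",
    CORE: "core",
    GROUND_GLASS: "ground-glass",
}

#: The three foreground classes, in likelihood-vector column order (v, c, g).
FOREGROUND_CLASSES = (VESSEL, CORE, GROUND_GLASS)

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume:
    """A 3D scalar grid in Hounsfield units with physical metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values (HU for CT input).
    spacing : tuple of float
        Per-axis voxel size in mm, ``(z, y, x)`` order; strictly positive.
    origin : tuple of float
        Physical coordinates (mm) of voxel ``(0, 0, 0)``.
    meta : dict
        Free-form provenance (resampling rule, normalization profile, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def with_data(self, data: np.ndarray, **meta) -> "Volume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, data=data, meta={**self.meta, **meta})


@dataclass
class LabelMap:
    """A 3D integer grid aligned to a :class:`Volume`.

    Values follow the project legend (0 background, 1 vessel, 2 core,
    3 ground-glass); binary masks use 0/1.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise ValueError(f"LabelMap data must be integer, got dtype {self.data.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self) -> np.ndarray:
        """Boolean foreground mask (any nonzero label)."""
        return self.data > 0

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return replace(self, data=data)


def same_grid(a, b, tol: float = 1e-6) -> bool:
    """Whether two grids share shape, spacing and origin (within ``tol`` mm)."""
    return (
        a.shape == b.shape
        and all(abs(x - y) <= tol for x, y in zip(a.spacing, b.spacing))
        and all(abs(x - y) <= tol for x, y in zip(a.origin, b.origin))
    )


def require_same_grid(a, b, what: str = "inputs") -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"{what} are not on the same grid: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}"
        )


def _check_path(path: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    low = path.lower()
    if not any(low.endswith(ext) for ext in _SUPPORTED_EXT):
        raise ValueError(f"unsupported volume format for {path}; expected one of {_SUPPORTED_EXT}")


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    _check_path(path)
    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(data=data, spacing=spacing, origin=origin)


def read_labelmap(path: str) -> LabelMap:
    """Read a label/mask volume; values are rounded to the nearest integer."""
    vol = read_volume(path)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int16)
    return LabelMap(data=data, spacing=vol.spacing, origin=vol.origin)


def write_volume(vol, path: str) -> None:
    """Write a :class:`Volume` or :class:`LabelMap` (format from extension)."""
    low = path.lower()
    if not any(low.endswith(ext) for ext in _SUPPORTED_EXT):
        raise ValueError(f"unsupported volume format for {path}; expected one of {_SUPPORTED_EXT}")
    data = vol.data
    if isinstance(vol, LabelMap):
        data = data.astype(np.int16)
    elif data.dtype not in (np.int16, np.float32):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, path, useCompression=low.endswith(".nii.gz"))
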