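"""Volumetric image container and NIfTI I/O.

A :class:`CTVolume` is the unit of image exchange across the pipeline:
a 3-D array of Hounsfield units plus the physical grid (voxel spacing in
mm and world origin).  Arrays are indexed ``data[i, j, k]`` along the
world x, y, z axes; voxel ``(i, j, k)`` has its centre at
``origin + (i*sx, j*sy, k*sz)``.  Out-of-field voxels produced by
resampling are carried as NaN, never as fake tissue values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ValidationError

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """3-D CT volume in Hounsfield units on a regular grid."""

    data: np.ndarray                       # (nx, ny, nz), HU
    spacing: tuple[float, float, float]    # mm per voxel along x, y, z
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    # -- grid helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "CTVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open grids of voxel-centre world coordinates (mm) along x, y, z."""
        ax = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing, self.origin, dict(self.meta))

    # -- SimpleITK bridge ---------------------------------------------

    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are indexed (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, meta: dict | None = None) -> "CTVolume":
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()), meta or {})

    # -- NIfTI I/O -----------------------------------------------------

    def save(self, path: str) -> None:
        """Write as NIfTI; HU as float32 (or int16 if lossless)."""
        data = self.data
        if np.isfinite(data).all() and np.allclose(data, np.round(data)):
            lo, hi = data.min(), data.max()
            if lo >= np.iinfo(np.int16).min and hi <= np.iinfo(np.int16).max:
                data = data.astype(np.int16)
        vol = CTVolume(data.astype(np.float32) if data.dtype.kind == "f" else data,
                       self.spacing, self.origin)
        sitk.WriteImage(vol.to_sitk(), path)

    @classmethod
    def load(cls, path: str) -> "CTVolume":
        return cls.from_sitk(sitk.ReadImage(path))
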