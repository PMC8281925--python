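"""Volumetric image container with physical spacing and origin.

Voxel arrays are indexed ``[x, y, z]``; the world position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (voxel-centre
convention).  I/O goes through SimpleITK, which handles NIfTI and
MetaImage transparently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class VolumeImage:
    voxels: np.ndarray          # (nx, ny, nz) scalar grid
    spacing: np.ndarray         # (3,) mm, strictly positive
    origin: np.ndarray          # (3,) mm, world position of voxel (0,0,0) centre

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D grid")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        if voxels.shape != self.voxels.shape:
            raise ValueError("replacement grid must match existing shape")
        return VolumeImage(voxels=voxels, spacing=self.spacing.copy(), origin=self.origin.copy())


def read_volume(path: str | Path) -> VolumeImage:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return VolumeImage(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))
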