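"""Voxel-stack container for serial-section EM volumes.

A stack is a 3D grayscale array with anisotropic physical voxel sizes.
FIB/SEM stacks are strongly anisotropic: a few nm per pixel in the imaging
plane and a much larger section thickness (here 20 nm) along z.

Conventions
-----------
* ``data`` is indexed ``[z, y, x]`` (one TIFF page per section, z ascending).
* ``voxel_size_nm`` is given in ``(x, y, z)`` order, matching how voxel
  sizes are quoted for micrographs (in-plane resolution first).
* The center of voxel ``(0, 0, 0)`` sits at physical coordinate ``(0, 0, 0)``
  and physical positions are reported in ``(x, y, z)`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ValidationError


@dataclass
class VoxelStack:
    """3D grayscale volume with per-axis physical voxel size."""

    data: np.ndarray                      # (z, y, x)
    voxel_size_nm: tuple[float, float, float]   # (vx, vy, vz)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError("stack data must be a non-empty 3D array")
        vs = tuple(float(v) for v in self.voxel_size_nm)
        if len(vs) != 3 or not all(np.isfinite(v) and v > 0 for v in vs):
            raise ValidationError(f"voxel sizes must be finite and positive, got {vs}")
        self.voxel_size_nm = vs

    # -- geometry -------------------------------------------------------
    @property
    def shape_voxels(self) -> tuple[int, int, int]:
        """Stack shape in (x, y, z) order."""
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def voxel_volume_nm3(self) -> float:
        vx, vy, vz = self.voxel_size_nm
        return vx * vy * vz

    def physical_coords(self, voxels: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) nm coordinates of voxel indices given as (N, 3) [z, y, x]."""
        voxels = np.atleast_2d(np.asarray(voxels))
        vx, vy, vz = self.voxel_size_nm
        return np.column_stack(
            [voxels[:, 2] * vx, voxels[:, 1] * vy, voxels[:, 0] * vz]
        ).astype(float)

    # -- IO -------------------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as a multi-page TIFF, one page per section, z ascending."""
        tifffile.imwrite(str(path), self.data, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, voxel_size_nm) -> "VoxelStack":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, voxel_size_nm=tuple(voxel_size_nm))


@dataclass
class LabelVolume:
    """Ground-truth labels parallel to a rendered stack.

    ``ids`` holds the phantom id (0 = background) and ``side`` which side of
    the apposition surface a voxel belongs to (1 = postsynaptic side,
    2 = presynaptic side, 0 = background).  The cleft is split at the
    apposition surface so that the post/pre voxel interface coincides with it.
    """

    ids: np.ndarray     # uint16, (z, y, x)
    side: np.ndarray    # uint8, (z, y, x)
    voxel_size_nm: tuple[float, float, float] = field(default=(3.7, 3.7, 20.0))

    def to_tiff(self, ids_path, side_path=None) -> None:
        tifffile.imwrite(str(ids_path), self.ids.astype(np.uint16),
                         photometric="minisblack")
        if side_path is not None:
            tifffile.imwrite(str(side_path), self.side.astype(np.uint8),
                             photometric="minisblack")
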