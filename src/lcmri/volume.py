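"""In-memory volume container and NIfTI I/O.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
(``(x, y, z, t)`` for BOLD), with the third axis holding axial slices and the
slice index increasing in the superior (rostral) direction.  The in-plane
convention is ``+x`` left-to-right and ``+y`` anterior-to-posterior, so
"anterior to" a voxel means a *smaller* y index.  Voxel indexing is 0-based
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "load_volume", "save_volume"]


@dataclass
class Volume:
    """A 3D (or 4D for BOLD) intensity array with physical voxel dimensions.

    Parameters
    ----------
    data:
        Intensity array indexed ``(x, y, z[, t])``.
    voxel_size:
        Edge length in mm along each spatial axis; all entries > 0.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3:
            raise ValueError("voxel_size must have exactly 3 entries")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_slices(self) -> int:
        """Number of axial slices (third axis)."""
        return self.data.shape[2]

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine (no rotation, origin at voxel 0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)


def save_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI with the voxel size recorded in the header."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine())
    zooms = vol.voxel_size if not vol.is_4d else (*vol.voxel_size, 1.0)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, voxel_size, path) -> None:
    """Write a binary mask as uint8 NIfTI."""
    vol = Volume(np.asarray(mask, dtype=np.uint8), tuple(voxel_size))
    img = nib.Nifti1Image(vol.data, vol.affine())
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def load_volume(path) -> Volume:
    """Read a NIfTI file into a :class:`Volume` (voxel size from the header)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return Volume(data, tuple(float(z) for z in zooms))


def load_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI mask; returns (boolean array, voxel size)."""
    vol = load_volume(path)
    return vol.data > 0, vol.voxel_size
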