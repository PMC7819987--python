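"""3-D noncontrast-CT volume container with anisotropic voxel spacing.

Axis convention: ``voxels[i, j, k]`` with physical coordinates
``origin_mm + (i + 0.5, j + 0.5, k + 0.5) * spacing_mm`` for the voxel
*center*.  The third axis is conventionally the slice (z) axis, but nothing
downstream assumes that: all geometry is computed in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: default acquisition grid: 0.5 mm in-plane, 5 mm slice thickness
DEFAULT_SPACING_MM = (0.5, 0.5, 5.0)


@dataclass
class CTVolume:
    """A CT scan as a grid of Hounsfield-unit values.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values; must lie within the representable CT range
        [-1024, 3071].
    spacing_mm : tuple of float
        Strictly positive voxel edge lengths in mm.
    origin_mm : tuple of float
        Physical position of the corner of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if any(s < m for s, m in zip(self.voxels.shape, (16, 16, 4))):
            raise ValueError(
                f"volume shape {self.voxels.shape} below minimum (16, 16, 4)"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive lengths")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU range [{lo:.1f}, {hi:.1f}] outside [{HU_MIN}, {HU_MAX}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def voxel_centers_mm(self, index_array: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of voxels given as an (n, 3) index array."""
        idx = np.asarray(index_array, dtype=float)
        return (idx + 0.5) * np.asarray(self.spacing_mm) + np.asarray(
            self.origin_mm
        )

    # ------------------------------------------------------------------ I/O

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.voxels, self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(o) for o in aff[:3, 3])
        return cls(
            np.asarray(img.get_fdata(), dtype=np.float32),
            spacing_mm=spacing,
            origin_mm=origin,
        )


def save_label_map(mask_or_labels: np.ndarray, like: CTVolume, path) -> None:
    """Write an integer label map aligned with ``like`` as NIfTI."""
    arr = np.asarray(mask_or_labels).astype(np.int16)
    nib.save(nib.Nifti1Image(arr, like.affine()), str(path))
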