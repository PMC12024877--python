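"""Volumetric containers and NIfTI I/O.

A :class:`Volume` is a 3-D scalar grid with physical voxel spacing (mm) and a
world-coordinate affine, the minimal metadata the rest of the package needs:
defect sizes are specified in millimetres, and surface-distance metrics are
spacing-aware.

Axis convention: ``data`` is indexed ``(D, W, H)`` where axis 1 (``W``) is the
left-right axis.  The midsagittal plane is the central index plane of axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "save_nifti", "load_nifti"]


@dataclass
class Volume:
    """A 3-D image or mask with voxel spacing in mm.

    Parameters
    ----------
    data
        3-D array, indexed ``(D, W, H)``; binary masks hold only {0, 1}.
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World coordinate of voxel (0, 0, 0) in mm.
    meta
        Free-form metadata (the skull phantom stores its anatomical zone
        label map here).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every Volume axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal: axis-aligned grids only)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin, dict(self.meta))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def save_nifti(vol: Volume, path: str | Path, dtype=np.uint8) -> Path:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz); binary masks as uint8."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> Volume:
    """Read a NIfTI file back into a :class:`Volume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data, zooms, origin)
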