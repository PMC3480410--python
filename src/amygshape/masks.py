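"""Binary segmentation masks with voxel-to-world geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class BinaryMask:
    """A 3D binary voxel grid with an affine mapping indices to mm.

    ``grid`` holds {0,1}; ``affine`` is a 4x4 voxel-index -> world (mm)
    transform.  Only axis-aligned affines with isotropic or anisotropic
    positive spacing are produced by this package, but any invertible
    affine round-trips through NIfTI.
    """

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("mask grid must be binary")
        self.grid = self.grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.grid.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        grid = (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
        return cls(grid=grid, affine=np.asarray(img.affine))
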