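"""3-D Hounsfield-unit volumes and binary masks, with NIfTI round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "BinaryMask3D"]


@dataclass
class CTVolume:
    """A CT-like scalar grid in Hounsfield units (HU) with voxel spacing in mm."""

    hu: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("hu grid must be 3-D")
        if not np.isfinite(self.hu).all():
            raise ValueError("hu grid must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    def _affine(self) -> np.ndarray:
        return np.diag([*self.spacing, 1.0])

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), self._affine()), str(path))

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(hu=np.asarray(img.dataobj, dtype=float), spacing=spacing)


@dataclass
class BinaryMask3D:
    """Boolean mask on the same grid as its volume; serialised as 0/1 integers."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(
            self.values.astype(np.uint8), np.diag([*self.spacing, 1.0])
        )
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "BinaryMask3D":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(values=np.asarray(img.dataobj) > 0, spacing=spacing)
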