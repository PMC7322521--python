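"""Regular-lattice scalar volumes (T1 images, masks) with NIfTI-1 I/O."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError


@dataclass
class VolumeImage:
    """A scalar grid on a regular 3-D lattice with a lattice-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise IntegrityError(f"volume must be a non-empty 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise IntegrityError("affine must be 4x4")
        if (self.voxel_sizes <= 0).any():
            raise IntegrityError("voxel sizes must be strictly positive")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_lattice(self, other: "VolumeImage") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-9
        )


@dataclass
class MaskVolume(VolumeImage):
    """A binary volume on the subject lattice with a provenance tag."""

    tag: str = "lesion"

    def __post_init__(self):
        super().__post_init__()
        if not np.isin(self.data, (0.0, 1.0)).all():
            raise IntegrityError("mask volume must contain only 0/1")
        if self.tag not in ("lesion", "brain", "composite-support"):
            raise IntegrityError(f"unknown mask tag {self.tag!r}")

    @property
    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


def load_volume(path) -> VolumeImage:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    return VolumeImage(np.asanyarray(img.dataobj, dtype=np.float64), img.affine)


def load_mask(path, tag: str = "lesion") -> MaskVolume:
    vol = load_volume(path)
    return MaskVolume(vol.data, vol.affine, tag=tag)


def save_volume(vol: VolumeImage, path, dtype=np.float32) -> None:
    import nibabel as nib

    if isinstance(vol, MaskVolume):
        dtype = np.uint8
    nib.save(nib.Nifti1Image(vol.data.astype(dtype), vol.affine), os.fspath(path))
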