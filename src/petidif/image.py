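"""4-D dynamic PET volume container with NIfTI-1 round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import FrameSchedule, TimeActivityCurve


@dataclass
class DynamicImage:
    """Voxel activity in kBq/mL indexed (x, y, z, frame), plus geometry.

    The frame axis length must match the schedule; voxel_size is isotropic mm.
    """

    voxels: np.ndarray
    voxel_size: float
    schedule: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis length must equal schedule length")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def n_planes(self) -> int:
        """Number of axial planes (z axis, feet-to-head by convention)."""
        return self.voxels.shape[2]

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size / 10.0) ** 3  # mm^3 -> mL

    def early_mean(self, n_frames: int = 10) -> np.ndarray:
        """Voxelwise mean of the first ``n_frames`` frames (3-D volume)."""
        if self.n_frames < n_frames:
            raise ValueError(f"image has {self.n_frames} frames, need {n_frames}")
        return self.voxels[..., :n_frames].mean(axis=3)

    def voxel_tac(self, idx) -> TimeActivityCurve:
        x, y, z = idx
        return TimeActivityCurve(self.schedule.mid_times, self.voxels[x, y, z, :])

    def save(self, path: str | Path) -> None:
        """Write a NIfTI-1 4-D volume plus a ``.frames.json`` sidecar."""
        path = Path(path)
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), path)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        sidecar = Path(str(sidecar) + ".frames.json")
        sidecar.write_text(json.dumps(self.schedule.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DynamicImage":
        path = Path(path)
        img = nib.load(path)
        sidecar = path.with_suffix("").with_suffix("")
        sidecar = Path(str(sidecar) + ".frames.json")
        schedule = FrameSchedule.from_dict(json.loads(sidecar.read_text()))
        voxel_size = float(img.header.get_zooms()[0])
        return cls(np.asarray(img.dataobj, dtype=float), voxel_size, schedule)
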