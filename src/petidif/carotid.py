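"""Carotid-signal (CS) whole-blood extraction from the dynamic image.

The internal carotids are segmented by thresholding the mean of the early
frames at a fraction of its maximum, restricted to the lowest axial planes
(feet-to-head axis); the whole-blood TAC is then the per-frame mean of the
ten hottest masked voxels of each plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import TimeActivityCurve
from .image import DynamicImage


@dataclass
class CarotidMask:
    voxel_indices: np.ndarray  # (N, 3) int array of (x, y, z)
    plane_range: tuple[int, int]  # [lo, hi) axial index interval
    threshold_used: float  # kBq/mL

    def __post_init__(self):
        if self.voxel_indices.size == 0:
            raise ValueError("carotid mask is empty")
        z = self.voxel_indices[:, 2]
        if z.min() < self.plane_range[0] or z.max() >= self.plane_range[1]:
            raise ValueError("mask voxels outside the plane range")

    def __len__(self) -> int:
        return self.voxel_indices.shape[0]

    def as_volume(self, shape) -> np.ndarray:
        vol = np.zeros(shape, dtype=bool)
        vol[tuple(self.voxel_indices.T)] = True
        return vol


def build_carotid_mask(img: DynamicImage, n_early_frames: int = 10,
                       threshold_frac: float = 0.48, n_planes: int = 36,
                       lowest_is_low_index: bool = True) -> CarotidMask:
    """Threshold the early-frame mean image at ``threshold_frac`` x its global
    maximum, keeping only the lowest ``n_planes`` axial planes.

    The boundary is inclusive (mean >= threshold). ``lowest_is_low_index``
    flips which end of the z axis is "feet" when the orientation convention
    differs.
    """
    if img.n_planes < n_planes:
        raise ValueError(f"image has {img.n_planes} planes, need >= {n_planes}")
    mean_img = img.early_mean(n_early_frames)
    threshold = threshold_frac * float(mean_img.max())
    mask = mean_img >= threshold
    nz = img.n_planes
    if lowest_is_low_index:
        plane_range = (0, n_planes)
        mask[:, :, n_planes:] = False
    else:
        plane_range = (nz - n_planes, nz)
        mask[:, :, : nz - n_planes] = False
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError(
            "empty carotid mask: no early-mean voxel reaches "
            f"{threshold_frac:.2f} x max within the lowest {n_planes} planes; "
            "try lowering the threshold")
    return CarotidMask(idx, plane_range, threshold)


def extract_hottest_tac(img: DynamicImage, mask: CarotidMask,
                        n_hot: int = 10, fixed_voxels: bool = False,
                        n_early_frames: int = 10) -> TimeActivityCurve:
    """Whole-blood TAC as the mean of the ``n_hot`` hottest masked voxels per
    axial plane, averaged over all planes the mask touches.

    By default the hottest voxels are re-selected in every frame; with
    ``fixed_voxels`` they are chosen once from the early-frame mean. Ties at
    the selection boundary are all included (the mean is over however many
    voxels tie in), so the result does not depend on voxel ordering.
    """
    if len(mask) == 0:
        raise ValueError("empty carotid mask")
    vol_mask = mask.as_volume(img.shape[:3])
    planes = np.unique(mask.voxel_indices[:, 2])
    n_frames = img.n_frames
    values = np.empty(n_frames)

    def hottest(vals: np.ndarray, ref: np.ndarray) -> np.ndarray:
        """Values whose reference rank is within the top n_hot, ties included."""
        if ref.size <= n_hot:
            return vals
        cut = np.sort(ref)[-n_hot]
        return vals[ref >= cut]

    if fixed_voxels:
        early = img.early_mean(n_early_frames)
    for f in range(n_frames):
        selected = []
        for z in planes:
            in_plane = vol_mask[:, :, z]
            frame_vals = img.voxels[:, :, z, f][in_plane]
            ref = early[:, :, z][in_plane] if fixed_voxels else frame_vals
            selected.append(hottest(frame_vals, ref))
        values[f] = float(np.mean(np.concatenate(selected)))
    return TimeActivityCurve(img.schedule.mid_times, values, name="CS")
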