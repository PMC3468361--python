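"""Volume-of-interest tooling for static FDG and dynamic water volumes.

Workflow mirrored here: the reference tumour VOI is drawn on the FDG image by
relative thresholding (75 % of the in-tumour maximum), carried over to the
water study through a rigid translation estimated from the two attenuation
images, and the aorta VOI is drawn on an early summed dynamic water image.
VOI-mean time-activity curves then feed the kinetic analysis.

Images live in voxel-index space, 0-based, axes ordered (x, y, z[, frame])
with the frame axis last (the NIfTI convention as read by nibabel).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError, ParameterError
from .kinetics import FrameSchedule, TimeActivityCurve

MODALITIES = ("FDG-SUV", "water-dynamic", "water-summed", "attenuation")


@dataclass(frozen=True)
class VolumeImage:
    """3-D static or 4-D dynamic voxel volume with physical voxel size (mm)."""

    data: np.ndarray
    voxel_size_mm: tuple
    modality: str
    schedule: FrameSchedule | None = None
    decay_corrected: bool = True

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if data.ndim not in (3, 4):
            raise ParameterError("volume must be 3-D (static) or 4-D (dynamic)")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError("voxel sizes must be three positive numbers (mm)")
        if self.modality not in MODALITIES:
            raise ParameterError(f"modality must be one of {MODALITIES}")
        if data.ndim == 4:
            if self.schedule is None:
                raise ParameterError("4-D volume needs a frame schedule")
            if data.shape[3] != self.schedule.n_frames:
                raise GridMismatchError("frame axis length != schedule frame count")

    @property
    def is_dynamic(self) -> bool:
        return self.data.ndim == 4

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path, modality: str,
                   schedule: FrameSchedule | None = None,
                   decay_corrected: bool = True) -> "VolumeImage":
        img = nib.load(str(Path(path)))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata()), vox, modality, schedule, decay_corrected)


@dataclass(frozen=True)
class VOIMask:
    """Boolean voxel set on a VolumeImage grid, with provenance."""

    voxels: np.ndarray
    voxel_size_mm: tuple
    provenance: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=bool)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if vox.ndim != 3:
            raise ParameterError("mask must be 3-D")
        if not vox.any():
            raise DegenerateInputError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size_mm)) / 1000.0

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))


def threshold_voi(image: VolumeImage, fraction: float = 0.75) -> VOIMask:
    """Voxels >= fraction * global maximum, restricted to the connected
    component containing the maximum voxel (26-connectivity)."""
    if image.is_dynamic:
        raise ParameterError("threshold_voi expects a static 3-D image")
    if not (0.0 < fraction < 1.0):
        raise ParameterError("threshold fraction must lie in (0, 1)")
    data = image.data
    peak = data.max()
    if peak <= 0:
        raise DegenerateInputError("image has no positive voxels to threshold")
    above = data >= fraction * peak
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    peak_label = labels[np.unravel_index(np.argmax(data), data.shape)]
    return VOIMask(labels == peak_label, image.voxel_size_mm,
                   provenance=f"threshold {fraction:.2f} x max on {image.modality}")


@dataclass(frozen=True)
class RegistrationResult:
    shift_voxels: tuple
    correlation: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_attenuation(moving: VolumeImage, fixed: VolumeImage,
                         search_window_mm: float = 16.0) -> RegistrationResult:
    """Rigid integer-voxel translation aligning two attenuation volumes.

    Exhaustive search over shifts within +/- search_window_mm per axis,
    maximising normalised cross-correlation on the overlap; ties are broken
    toward the smallest shift norm.  The winning correlation is exposed for QC
    (a low value flags an unreliable alignment).
    """
    if moving.modality != "attenuation" or fixed.modality != "attenuation":
        raise ParameterError("registration operates on attenuation volumes")
    if moving.spatial_shape != fixed.spatial_shape:
        raise GridMismatchError("attenuation volumes must share a grid")
    half = tuple(int(np.floor(search_window_mm / v)) for v in fixed.voxel_size_mm)
    if any(2 * h + 1 > s for h, s in zip(half, fixed.spatial_shape)):
        raise ParameterError("search window larger than the image")
    shape = fixed.spatial_shape
    best = None
    for dx in range(-half[0], half[0] + 1):
        for dy in range(-half[1], half[1] + 1):
            for dz in range(-half[2], half[2] + 1):
                shift = (dx, dy, dz)
                src = tuple(slice(max(-s, 0), min(n, n - s)) for n, s in zip(shape, shift))
                dst = tuple(slice(max(s, 0), min(n, n + s)) for n, s in zip(shape, shift))
                cc = _ncc(moving.data[src], fixed.data[dst])
                key = (-cc, dx * dx + dy * dy + dz * dz)
                if best is None or key < best[0]:
                    best = (key, shift, cc)
    return RegistrationResult(shift_voxels=best[1], correlation=best[2])


def _translate(data: np.ndarray, shift) -> np.ndarray:
    """Shift array content by integer voxels, zero-filling exposed regions."""
    out = np.zeros_like(data)
    lengths = [max(n - abs(s), 0) for n, s in zip(data.shape[:3], shift)]
    if min(lengths) == 0:
        return out
    src = tuple(slice(max(-s, 0), max(-s, 0) + ln) for s, ln in zip(shift, lengths))
    dst = tuple(slice(max(s, 0), max(s, 0) + ln) for s, ln in zip(shift, lengths))
    out[dst] = data[src]
    return out


def transfer_voi(mask: VOIMask, shift) -> VOIMask:
    """Translate a VOI by an integer-voxel shift, cropping at the boundary."""
    shift = tuple(int(s) for s in shift)
    moved = _translate(mask.voxels, shift)
    if not moved.any():
        raise DegenerateInputError("VOI fully shifted out of the image bounds")
    return VOIMask(moved, mask.voxel_size_mm,
                   provenance=f"{mask.provenance} + shift {shift}")


def summed_image(dynamic: VolumeImage, frame_range=None) -> VolumeImage:
    """Duration-weighted sum over selected frames of a dynamic volume.

    ``frame_range`` is an iterable of frame indices; default: all frames whose
    start lies within the first 30 s (the early bolus-transit window used to
    delineate the descending aorta).
    """
    if not dynamic.is_dynamic:
        raise ParameterError("summed_image expects a 4-D dynamic volume")
    sched = dynamic.schedule
    if frame_range is None:
        frame_range = [i for i in range(sched.n_frames) if sched.frame_start[i] < 30.0]
    idx = [int(i) for i in frame_range]
    if len(idx) == 0:
        raise ParameterError("empty frame range")
    if min(idx) < 0 or max(idx) >= sched.n_frames:
        raise ParameterError("frame index out of range")
    out = np.tensordot(dynamic.data[..., idx], sched.frame_duration[idx], axes=([3], [0]))
    return VolumeImage(out, dynamic.voxel_size_mm, "water-summed")


def extract_tac(dynamic: VolumeImage, mask: VOIMask) -> TimeActivityCurve:
    """Per-frame VOI-mean activity of a dynamic volume."""
    if not dynamic.is_dynamic:
        raise ParameterError("extract_tac expects a 4-D dynamic volume")
    if mask.voxels.shape != dynamic.spatial_shape:
        raise GridMismatchError("mask grid does not match the dynamic volume")
    series = dynamic.data[mask.voxels].mean(axis=0)
    return TimeActivityCurve(dynamic.schedule, series, dynamic.decay_corrected)
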