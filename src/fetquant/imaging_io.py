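"""Volumetric data model and NIfTI I/O for static and dynamic PET.

The spatial data model is deliberately small: a :class:`VolumeGrid` holds a
3-D standardized-uptake-value (SUV) field together with its NIfTI affine, a
:class:`Mask` is a binary field sharing that geometry, and a
:class:`DynamicSeries` stacks per-frame SUV fields over a
:class:`FrameSchedule` of acquisition windows.

Conventions used throughout the package:

* voxel indices are 0-based, in (x, y, z) order with z the axial slice axis;
* world coordinates come from the NIfTI voxel-to-world affine;
* SUV is unitless (body-weight normalized); small reconstruction negatives
  are clamped to zero on load and the clamp count is logged;
* masks must live on the exact grid of their reference volume — a geometry
  mismatch is a hard error, never a silent resample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

log = logging.getLogger(__name__)

MASK_LABELS = (
    "pet_segmentation",
    "flair",
    "ce",
    "background_roi",
    "isocontour_roi",
)

_AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass(eq=False)
class VolumeGrid:
    """A 3-D scalar SUV field with voxel spacing and world affine.

    Parameters
    ----------
    values
        3-D float array of SUV, non-negative and finite.
    affine
        4x4 voxel-to-world transform (NIfTI convention, mm).
    n_clamped
        Number of negative voxels clamped to zero on load (bookkeeping).
    """

    values: np.ndarray
    affine: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")
        if np.any(self.values < 0):
            raise ValueError("volume contains negative SUV; clamp on load")
        if np.any(self.spacing <= 0):
            raise ValueError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "VolumeGrid | Mask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL
        )


@dataclass(eq=False)
class Mask:
    """A binary field aligned to a reference :class:`VolumeGrid`."""

    values: np.ndarray
    affine: np.ndarray
    label: str = "pet_segmentation"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be strictly binary, found values {uniq[:5]}")
        self.values = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml

    def indices(self) -> np.ndarray:
        """(n, 3) array of voxel indices inside the mask."""
        return np.argwhere(self.values > 0)


def check_same_grid(a: VolumeGrid | Mask, b: VolumeGrid | Mask) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape and affine."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=_AFFINE_ATOL):
        raise GridMismatchError("affine mismatch between grids")


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition windows of a dynamic scan, in minutes p.i.

    Frames are (start, end) pairs; they must be non-overlapping, strictly
    increasing, with end > start. Mid-times, used as the time axis of
    time–activity curves, are (start + end) / 2.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(s), float(e)) for s, e in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("schedule has no frames")
        prev_end = None
        for s, e in frames:
            if e <= s:
                raise ValueError(f"frame ({s}, {e}) has end <= start")
            if prev_end is not None and s < prev_end - 1e-9:
                raise ValueError("schedule frames overlap or are out of order")
            prev_end = e
        if frames[0][0] < 0:
            raise ValueError("first frame starts before injection (t < 0)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def mid_times(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.frames])

    @property
    def span(self) -> tuple[float, float]:
        return self.frames[0][0], self.frames[-1][1]

    @classmethod
    def from_file(cls, path: str | Path) -> "FrameSchedule":
        """Load a schedule from a JSON or YAML list of [start, end] pairs."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(tuple((float(s), float(e)) for s, e in raw))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([list(f) for f in self.frames]))


#: Default 0–40 min schedule; its mid-times (2.5, 7.5, 12.5, 17.5, 25, 35 min)
#: are the levels at which TTP values are reported clinically.
DEFAULT_SCHEDULE = FrameSchedule(
    ((0, 5), (5, 10), (10, 15), (15, 20), (20, 30), (30, 40))
)


@dataclass(eq=False)
class DynamicSeries:
    """A 4-D dynamic PET series: one 3-D SUV field per schedule frame."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count mismatch: data has {self.data.shape[3]} frames, "
                f"schedule has {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, i: int) -> VolumeGrid:
        return VolumeGrid(self.data[..., i], self.affine)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3-D SUV volume from a NIfTI-1/2 file.

    Negative voxels (common reconstruction noise) are clamped to zero; the
    number clamped is logged and kept on the returned grid. Non-finite
    voxels are an error.
    """
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4:
        raise ValueError(f"{path} is 4-D; use read_dynamic with a frame schedule")
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} dimensions, expected 3")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite voxels")
    n_clamped = int(np.count_nonzero(data < 0))
    if n_clamped:
        log.warning("%s: clamped %d negative voxels to 0", path, n_clamped)
        data = np.clip(data, 0, None)
    return VolumeGrid(data, img.affine, n_clamped=n_clamped)


def read_dynamic(path: str | Path, schedule: FrameSchedule) -> DynamicSeries:
    """Read a 4-D dynamic PET series whose 4th axis matches the schedule."""
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path} has {data.ndim} dimensions, expected 4")
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"{path}: {data.shape[3]} frames but schedule has {len(schedule)}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite voxels")
    n_clamped = int(np.count_nonzero(data < 0))
    if n_clamped:
        log.warning("%s: clamped %d negative voxels to 0", path, n_clamped)
        data = np.clip(data, 0, None)
    return DynamicSeries(data, img.affine, schedule)


def read_mask(
    path: str | Path,
    reference: VolumeGrid | None = None,
    label: str = "pet_segmentation",
) -> Mask:
    """Read a binary mask; values > 0.5 are foreground.

    When a reference grid is given, shape and affine must match exactly.
    """
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} dimensions, expected 3")
    mask = Mask((data > 0.5).astype(np.uint8), img.affine, label=label)
    if reference is not None:
        check_same_grid(reference, mask)
    return mask


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), volume.affine), str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine), str(path))


def write_dynamic(series: DynamicSeries, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), series.affine), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def apply_affine_resample(
    mask: Mask, target: VolumeGrid, transform: np.ndarray
) -> Mask:
    """Resample a binary mask onto a target grid under a world-space affine.

    ``transform`` maps source world coordinates to target world coordinates
    (an externally estimated rigid/affine registration). Resampling is
    nearest-neighbour, so binaryness is preserved by construction. The
    transform must be invertible; a mask that lands entirely outside the
    target field of view yields an empty mask with a warning.
    """
    transform = np.asarray(transform, dtype=np.float64)
    if transform.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    det = np.linalg.det(transform)
    if abs(det) < 1e-12:
        raise ValueError("singular transform cannot be inverted")
    # target voxel -> target world -> source world -> source voxel
    full = np.linalg.inv(mask.affine) @ np.linalg.inv(transform) @ target.affine
    out = ndimage.affine_transform(
        mask.values,
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    result = Mask(out.astype(np.uint8), target.affine, label=mask.label)
    if result.is_empty and not mask.is_empty:
        log.warning("resampled mask is empty: source lies outside target field of view")
    return result
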