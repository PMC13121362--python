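"""Static [18F]FET PET quantification.

Implements the standard background-referenced workflow for amino-acid PET in
glioma: the mean SUV of a healthy contralateral background region defines a
segmentation threshold at 1.6x background; the supra-threshold tumour volume
yields SUV_max/SUV_mean and the tumour-to-background ratios
TBR_max = SUV_max / background and TBR_mean = SUV_mean / background.
A lesion with TBR_max >= 1.6 is amino-acid-PET positive (PET-RANO 1.0
criterion, closed boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import (
    DynamicSeries,
    Mask,
    VolumeGrid,
    check_same_grid,
)

log = logging.getLogger(__name__)

#: PET-RANO 1.0 positivity threshold on TBR_max (closed: >= is positive).
PET_POSITIVITY_TBR = 1.6

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean/SD SUV of the healthy contralateral background region."""

    mean_suv: float
    sd_suv: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.mean_suv <= 0:
            raise ValueError(f"background mean must be > 0, got {self.mean_suv}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the threshold segmentation.

    threshold_factor
        Multiplier on the background mean SUV; 1.6 is the standard clinical
        threshold for [18F]FET.
    connectivity
        Voxel neighbourhood for connected-component labelling (6/18/26).
    min_component_ml
        Components smaller than this are discarded as noise (0 disables).
    seed_point
        Optional voxel index; when given, only the component containing
        (or, if none contains it, nearest to) the seed is kept — a
        reproducible stand-in for semiautomatic operator selection.
    """

    threshold_factor: float = 1.6
    connectivity: int = 26
    min_component_ml: float = 0.1
    seed_point: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.threshold_factor <= 1:
            raise ValueError("threshold_factor must be > 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_component_ml < 0:
            raise ValueError("min_component_ml must be >= 0")


@dataclass(frozen=True)
class UptakeMetrics:
    """Per-lesion uptake metrics.

    For an empty segmentation (PET-negative tumour) the segment-based
    fields are None and TBR_max falls back to the global maximum within a
    search region, so negative cases still carry a measurable TBR_max.
    """

    suv_max: Optional[float]
    suv_mean: Optional[float]
    tbr_max: float
    tbr_mean: Optional[float]
    pet_volume_ml: float
    pet_positive: bool
    threshold_suv: float
    background_mean: float

    def __post_init__(self) -> None:
        if self.tbr_mean is not None and self.tbr_mean > self.tbr_max + 1e-12:
            raise ValueError("tbr_mean cannot exceed tbr_max")
        if self.pet_volume_ml < 0:
            raise ValueError("pet_volume_ml must be >= 0")

    def to_dict(self) -> dict:
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "tbr_max": self.tbr_max,
            "tbr_mean": self.tbr_mean,
            "pet_volume_ml": self.pet_volume_ml,
            "pet_positive": self.pet_positive,
            "threshold_suv": self.threshold_suv,
            "background_mean": self.background_mean,
        }


def estimate_background(
    volume: VolumeGrid, roi: Mask, min_voxels: int = 100
) -> BackgroundEstimate:
    """Mean/SD SUV over a background ROI on the volume's grid.

    The ROI must be non-empty and at least ``min_voxels`` large; a
    non-positive mean (e.g. an ROI placed outside the head) is an error
    because every downstream ratio divides by it.
    """
    check_same_grid(volume, roi)
    if roi.is_empty:
        raise ValueError("background ROI is empty")
    if roi.n_voxels < min_voxels:
        raise ValueError(
            f"background ROI has {roi.n_voxels} voxels, below minimum {min_voxels}"
        )
    vals = volume.values[roi.values > 0]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError(f"background mean SUV must be positive, got {mean}")
    return BackgroundEstimate(mean_suv=mean, sd_suv=float(vals.std()), n_voxels=roi.n_voxels)


def mirrored_background_roi(
    volume: VolumeGrid,
    centre: tuple[int, int, int],
    semi_axes_mm: tuple[float, float, float],
) -> Mask:
    """Build an ellipsoidal background ROI mirrored across the mid-sagittal plane.

    ``centre`` is a voxel index on the lesion side; the ROI is an ellipsoid of
    the given mm semi-axes centred at the x-mirrored position, a simple stand-in
    for a contralateral-hemisphere background region.
    """
    nx = volume.shape[0]
    mirrored = (nx - 1 - centre[0], centre[1], centre[2])
    vals = _ellipsoid_mask(volume.shape, mirrored, semi_axes_mm, volume.spacing)
    return Mask(vals, volume.affine, label="background_roi")


def _ellipsoid_mask(shape, centre, semi_axes_mm, spacing) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    out = np.zeros(shape, dtype=np.uint8)
    r = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        r += (((idx[ax] - centre[ax]) * spacing[ax]) / semi_axes_mm[ax]) ** 2
    out[r <= 1.0] = 1
    return out


def segment_lesion(
    volume: VolumeGrid,
    background: BackgroundEstimate,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[Mask, float]:
    """Threshold segmentation of the PET lesion.

    The threshold SUV is ``threshold_factor x background mean``; all voxels at
    or above it are candidate tumour. Connected components smaller than
    ``min_component_ml`` are discarded; with a seed point only the seed's
    (or nearest) component survives. An empty mask is a valid result
    (PET-negative tumour).

    Returns the segmentation mask and the threshold SUV used.
    """
    threshold = config.threshold_factor * background.mean_suv
    binary = volume.values >= threshold

    if config.seed_point is not None:
        seed = tuple(int(c) for c in config.seed_point)
        if any(c < 0 or c >= s for c, s in zip(seed, volume.shape)):
            raise ValueError(f"seed_point {seed} outside volume of shape {volume.shape}")

    if binary.any():
        structure = _CONNECTIVITY_STRUCTS[config.connectivity]
        labels, n = ndimage.label(binary, structure=structure)
        min_vox = config.min_component_ml / volume.voxel_volume_ml
        counts = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = counts[1:] >= min_vox
        if config.seed_point is not None:
            seed_label = labels[tuple(config.seed_point)]
            if seed_label != 0 and keep[seed_label]:
                chosen = seed_label
            else:
                chosen = _nearest_component(labels, keep, config.seed_point)
            keep[:] = False
            if chosen is not None:
                keep[chosen] = True
        binary = keep[labels]

    mask = Mask(binary.astype(np.uint8), volume.affine, label="pet_segmentation")
    return mask, float(threshold)


def _nearest_component(labels, keep, seed) -> Optional[int]:
    """Label of the surviving component closest to seed (voxel distance)."""
    best, best_d = None, np.inf
    seed = np.asarray(seed, dtype=np.float64)
    for lab in np.nonzero(keep)[0]:
        pts = np.argwhere(labels == lab)
        d = np.min(np.linalg.norm(pts - seed, axis=1))
        if d < best_d:
            best, best_d = int(lab), d
    return best


def compute_uptake_metrics(
    volume: VolumeGrid,
    segmentation: Mask,
    background: BackgroundEstimate,
    search_region: Optional[Mask] = None,
    positivity_tbr: float = PET_POSITIVITY_TBR,
    threshold_suv: Optional[float] = None,
) -> UptakeMetrics:
    """SUV/TBR metrics over the segmented lesion.

    With a non-empty segmentation, SUV_max/SUV_mean are taken over segmented
    voxels and divided by the background mean to give TBR_max/TBR_mean; the
    PET volume is the segmented voxel count times the voxel volume.

    With an empty segmentation (no supra-threshold uptake) segment-based
    metrics are absent and TBR_max is the global maximum SUV within
    ``search_region`` (whole volume when absent) over background — so
    PET-negative tumours still report a TBR_max, evaluated against the same
    positivity boundary.
    """
    check_same_grid(volume, segmentation)
    if background.mean_suv <= 0:
        raise ValueError("background mean must be positive")
    bg = background.mean_suv
    if threshold_suv is None:
        threshold_suv = PET_POSITIVITY_TBR * bg

    if not segmentation.is_empty:
        vals = volume.values[segmentation.values > 0]
        suv_max = float(vals.max())
        suv_mean = float(vals.mean())
        return UptakeMetrics(
            suv_max=suv_max,
            suv_mean=suv_mean,
            tbr_max=suv_max / bg,
            tbr_mean=suv_mean / bg,
            pet_volume_ml=segmentation.volume_ml,
            pet_positive=(suv_max / bg) >= positivity_tbr,
            threshold_suv=float(threshold_suv),
            background_mean=bg,
        )

    if search_region is not None:
        check_same_grid(volume, search_region)
        if search_region.is_empty:
            raise ValueError("search_region is empty")
        global_max = float(volume.values[search_region.values > 0].max())
    else:
        global_max = float(volume.values.max())
    tbr_max = global_max / bg
    return UptakeMetrics(
        suv_max=None,
        suv_mean=None,
        tbr_max=tbr_max,
        tbr_mean=None,
        pet_volume_ml=0.0,
        pet_positive=tbr_max >= positivity_tbr,
        threshold_suv=float(threshold_suv),
        background_mean=bg,
    )


def summation_image(
    series: DynamicSeries, window_start_min: float, window_end_min: float
) -> VolumeGrid:
    """Duration-weighted mean of frames inside [start, end] minutes.

    The window boundaries must coincide with frame boundaries of the
    schedule; partial-frame windows are rejected rather than interpolated.
    Standard windows are 20–40 min (static-equivalent summation) and
    10–30 min (isocontour definition for kinetics).
    """
    if window_end_min <= window_start_min:
        raise ValueError("window end must exceed start")
    lo, hi = series.schedule.span
    if window_start_min < lo - 1e-9 or window_end_min > hi + 1e-9:
        raise ValueError(
            f"window ({window_start_min}, {window_end_min}) outside schedule span ({lo}, {hi})"
        )
    boundaries = {s for s, _ in series.schedule.frames} | {e for _, e in series.schedule.frames}
    for b in (window_start_min, window_end_min):
        if not any(abs(b - x) < 1e-9 for x in boundaries):
            raise ValueError(f"window boundary {b} min does not align with frame boundaries")

    weights = []
    fields = []
    for i, (s, e) in enumerate(series.schedule.frames):
        if s >= window_start_min - 1e-9 and e <= window_end_min + 1e-9:
            weights.append(e - s)
            fields.append(series.data[..., i])
    if not fields:
        raise ValueError("window contains no complete frame")
    w = np.asarray(weights, dtype=np.float64)
    stacked = np.stack(fields, axis=-1)
    summed = np.tensordot(stacked, w, axes=([3], [0])) / w.sum()
    return VolumeGrid(summed, series.affine)
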