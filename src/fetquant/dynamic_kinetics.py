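"""Dynamic PET time–activity-curve (TAC) kinetics.

A tumour ROI is defined on the 10–30 min summation image with a 90%
isocontour of the maximum, applied uniformly to all dynamic frames to
extract TACs. Curves are classified into the three clinically used kinetic
families:

* **increasing** — SUV rises throughout the acquisition, or rises to a peak
  followed by a plateau;
* **decreasing** — an initial peak followed by a constant decline;
* **stable** — fluctuations staying within ±10% of the peak, with no clear
  trend.

Because those definitions are qualitative in clinical practice, this module
operationalizes them with explicit quantities (all configurable through
:class:`KineticConfig`): the earliest-maximum peak index ``p``, the relative
early-to-peak rise ``R = (s_p - s_early) / s_p`` and the relative late change
``Δ = (s_last - s_p) / s_p``.

Time-to-peak (TTP) is the mid-time of the earliest frame attaining the
curve's maximum. TTP_min is the shortest TTP observed in at least two
consecutive axial tumour slices; when no TTP value repeats across adjacent
slices, the whole-ROI TTP is used and flagged as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .imaging_io import DynamicSeries, Mask, VolumeGrid, check_same_grid

log = logging.getLogger(__name__)

CURVE_CLASSES = ("increasing", "stable", "decreasing")


@dataclass(frozen=True)
class KineticConfig:
    """Thresholds of the kinetic classification.

    isocontour_fraction
        ROI threshold as a fraction of the maximum on the 10–30 min
        summation image (0.90 standard).
    stability_band
        Relative half-width around the peak within which fluctuations count
        as "stable" / a plateau (0.10 standard).
    early_window_end_min
        Frames with mid-time up to this define the early uptake level used
        for the rise R.
    decline_threshold
        Relative post-peak drop below which a curve counts as decreasing.
    min_consecutive_slices
        Adjacent-slice support required for TTP_min and for a heterogeneous
        decreasing call.
    min_slice_voxels
        Slices contributing fewer ROI voxels are skipped in slice-wise
        analysis (single-voxel TACs are noise-dominated).
    """

    isocontour_fraction: float = 0.90
    stability_band: float = 0.10
    early_window_end_min: float = 5.0
    decline_threshold: float = 0.10
    min_consecutive_slices: int = 2
    min_slice_voxels: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.isocontour_fraction < 1:
            raise ValueError("isocontour_fraction must be in (0, 1)")
        if not 0 < self.stability_band < 1:
            raise ValueError("stability_band must be in (0, 1)")
        if self.min_consecutive_slices < 2:
            raise ValueError("min_consecutive_slices must be >= 2")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean ROI SUV per dynamic frame.

    ``roi_scope`` is "whole-roi" or "single-slice"; slice curves carry their
    axial slice index.
    """

    mid_times: np.ndarray
    values: np.ndarray
    roi_scope: str = "whole-roi"
    slice_index: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mid_times", np.asarray(self.mid_times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.mid_times.shape != self.values.shape or self.mid_times.ndim != 1:
            raise ValueError("mid_times and values must be 1-D of equal length")
        if len(self.mid_times) and np.any(np.diff(self.mid_times) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if self.roi_scope not in ("whole-roi", "single-slice"):
            raise ValueError(f"unknown roi_scope {self.roi_scope!r}")

    def __len__(self) -> int:
        return len(self.values)

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.mid_times, self.values * factor, self.roi_scope, self.slice_index
        )


@dataclass(frozen=True)
class KineticResult:
    """Tumour-level kinetic classification with slice-wise evidence."""

    curve_class: str
    per_slice_classes: tuple[str, ...]
    slice_indices: tuple[int, ...]
    ttp_per_slice: tuple[float, ...]
    ttp_min: float
    ttp_min_fallback: bool
    evidence: dict

    def __post_init__(self) -> None:
        if self.curve_class not in CURVE_CLASSES:
            raise ValueError(f"unknown curve class {self.curve_class!r}")

    def to_dict(self) -> dict:
        return {
            "curve_class": self.curve_class,
            "per_slice_classes": list(self.per_slice_classes),
            "slice_indices": list(self.slice_indices),
            "ttp_per_slice": list(self.ttp_per_slice),
            "ttp_min": self.ttp_min,
            "ttp_min_fallback": self.ttp_min_fallback,
            "evidence": self.evidence,
        }


# ---------------------------------------------------------------------------
# ROI definition and TAC extraction
# ---------------------------------------------------------------------------


def isocontour_roi(
    summation_10_30: VolumeGrid,
    fraction: float = 0.90,
    search_mask: Optional[Mask] = None,
) -> Mask:
    """Voxels at or above ``fraction`` x the maximum SUV (volumetric isocontour).

    The maximum is taken within ``search_mask`` when given, globally
    otherwise; voxels outside the search mask never enter the ROI. The ROI
    is non-empty by construction (the maximum voxel always qualifies); an
    all-zero summation image is rejected as degenerate.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    vals = summation_10_30.values
    if search_mask is not None:
        check_same_grid(summation_10_30, search_mask)
        if search_mask.is_empty:
            raise ValueError("search_mask is empty")
        region = search_mask.values > 0
    else:
        region = np.ones(vals.shape, dtype=bool)
    vmax = float(vals[region].max())
    if vmax <= 0:
        raise ValueError("summation image is all-zero within the search region")
    roi = (vals >= fraction * vmax) & region
    return Mask(roi.astype(np.uint8), summation_10_30.affine, label="isocontour_roi")


def extract_tac(series: DynamicSeries, roi: Mask) -> TimeActivityCurve:
    """Per-frame mean SUV over the ROI."""
    check_same_grid(series.frame(0), roi)
    if roi.is_empty:
        raise ValueError("ROI is empty")
    sel = roi.values > 0
    values = series.data[sel, :].mean(axis=0)
    return TimeActivityCurve(series.schedule.mid_times, values, roi_scope="whole-roi")


def extract_slice_tacs(
    series: DynamicSeries, roi: Mask, min_slice_voxels: int = 3
) -> list[TimeActivityCurve]:
    """One TAC per axial (z) slice intersecting the ROI, in slice order.

    Slices with fewer than ``min_slice_voxels`` ROI voxels are skipped and
    logged; they carry too few voxels for a stable mean.
    """
    check_same_grid(series.frame(0), roi)
    if roi.is_empty:
        raise ValueError("ROI is empty")
    mid = series.schedule.mid_times
    curves: list[TimeActivityCurve] = []
    n_skipped = 0
    for z in range(roi.shape[2]):
        sel = roi.values[:, :, z] > 0
        n = int(sel.sum())
        if n == 0:
            continue
        if n < min_slice_voxels:
            n_skipped += 1
            continue
        values = series.data[:, :, z, :][sel, :].mean(axis=0)
        curves.append(
            TimeActivityCurve(mid, values, roi_scope="single-slice", slice_index=z)
        )
    if n_skipped:
        log.info("skipped %d slices with < %d ROI voxels", n_skipped, min_slice_voxels)
    return curves


# ---------------------------------------------------------------------------
# Classification and TTP
# ---------------------------------------------------------------------------


def time_to_peak(curve: TimeActivityCurve) -> float:
    """Mid-time of the earliest frame attaining the curve maximum."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    p = int(np.argmax(curve.values))  # argmax returns the earliest maximum
    return float(curve.mid_times[p])


def classify_tac(
    curve: TimeActivityCurve, config: KineticConfig = KineticConfig()
) -> tuple[str, dict]:
    """Deterministic three-class kinetic call for one TAC.

    Rule, applied in order (s = curve values, p = earliest-max index,
    band = ``stability_band``):

    1. p at the final frame → increasing (continuous rise).
    2. Δ >= -band and R > band → increasing (rise then plateau).
    3. Δ < -decline_threshold and post-peak steps never rise by more than
       band x s_p → decreasing (peak then constant decline).
    4. all values within ± band x s_p of the peak → stable.
    5. otherwise: sign of the least-squares slope over the late window
       (mid-times past ``early_window_end_min``): positive → increasing,
       negative → decreasing, zero → stable.

    Returns the class and an evidence dict (p, R, Δ, rule fired).
    """
    s = curve.values
    t = curve.mid_times
    if len(s) < 4:
        raise ValueError("kinetic classification needs at least 4 frames")
    band = config.stability_band
    p = int(np.argmax(s))
    s_p = float(s[p])
    if s_p <= 0:
        raise ValueError("curve peak must be positive")
    early = s[t <= config.early_window_end_min]
    s_early = float(early.mean()) if early.size else float(s[0])
    rise = (s_p - s_early) / s_p
    late_change = (float(s[-1]) - s_p) / s_p

    evidence = {
        "peak_index": p,
        "relative_rise": rise,
        "relative_late_change": late_change,
    }

    if p == len(s) - 1:
        evidence["rule"] = "continuous-rise"
        return "increasing", evidence
    if late_change >= -band and rise > band:
        evidence["rule"] = "rise-then-plateau"
        return "increasing", evidence
    post = s[p:]
    steps_ok = bool(np.all(np.diff(post) <= band * s_p))
    if late_change < -config.decline_threshold and steps_ok:
        evidence["rule"] = "peak-then-decline"
        return "decreasing", evidence
    if np.all(np.abs(s - s_p) <= band * s_p):
        evidence["rule"] = "within-band"
        return "stable", evidence
    late_t = t[t > config.early_window_end_min]
    late_s = s[t > config.early_window_end_min]
    if late_t.size >= 2:
        slope = float(np.polyfit(late_t, late_s, 1)[0])
    else:
        slope = 0.0
    evidence["rule"] = "late-slope-sign"
    evidence["late_slope"] = slope
    if slope > 0:
        return "increasing", evidence
    if slope < 0:
        return "decreasing", evidence
    return "stable", evidence


def ttp_min(
    slice_curves: Sequence[TimeActivityCurve],
    config: KineticConfig = KineticConfig(),
    whole_roi_curve: Optional[TimeActivityCurve] = None,
) -> tuple[list[float], float, bool]:
    """TTP per slice and the minimal TTP with adjacent-slice support.

    TTP_min is the smallest TTP value shared by at least
    ``min_consecutive_slices`` adjacent axial slices (adjacency in slice
    index; skipped slices break a run). When no TTP repeats across adjacent
    slices, the whole-ROI curve's TTP is returned with the fallback flag set.

    Returns ``(ttp_per_slice, ttp_min, fallback)``.
    """
    if not slice_curves:
        raise ValueError("need at least one slice curve")
    order = np.argsort([c.slice_index if c.slice_index is not None else i
                        for i, c in enumerate(slice_curves)])
    curves = [slice_curves[i] for i in order]
    ttps = [time_to_peak(c) for c in curves]
    zs = [c.slice_index if c.slice_index is not None else i for i, c in enumerate(curves)]

    supported: list[float] = []
    run_len = 1
    for i in range(1, len(ttps)):
        adjacent = zs[i] == zs[i - 1] + 1
        if adjacent and ttps[i] == ttps[i - 1]:
            run_len += 1
        else:
            run_len = 1
        if run_len >= config.min_consecutive_slices:
            supported.append(ttps[i])
    if supported:
        return ttps, float(min(supported)), False
    if whole_roi_curve is None:
        raise ValueError(
            "no TTP repeats across adjacent slices and no whole-ROI curve "
            "was provided for the fallback"
        )
    log.info("TTP_min fallback: no adjacent-slice repeat, using whole-ROI TTP")
    return ttps, time_to_peak(whole_roi_curve), True


def classify_tumour_kinetics(
    slice_curves: Sequence[TimeActivityCurve],
    whole_roi_curve: TimeActivityCurve,
    config: KineticConfig = KineticConfig(),
) -> KineticResult:
    """Tumour-level kinetic call combining whole-ROI and slice-wise evidence.

    The tumour is decreasing when the whole-ROI curve classifies decreasing
    (homogeneous) or at least ``min_consecutive_slices`` adjacent slices each
    classify decreasing (heterogeneous); otherwise the whole-ROI class is
    used.
    """
    whole_class, evidence = classify_tac(whole_roi_curve, config)
    slice_classes = []
    zs = []
    for c in slice_curves:
        cls, _ = classify_tac(c, config)
        slice_classes.append(cls)
        zs.append(c.slice_index)

    heterogeneous_decreasing = False
    run = 0
    for i, cls in enumerate(slice_classes):
        adjacent = i > 0 and zs[i] is not None and zs[i - 1] is not None and zs[i] == zs[i - 1] + 1
        if cls == "decreasing":
            run = run + 1 if (run > 0 and adjacent) else 1
        else:
            run = 0
        if run >= config.min_consecutive_slices:
            heterogeneous_decreasing = True

    tumour_class = (
        "decreasing"
        if whole_class == "decreasing" or heterogeneous_decreasing
        else whole_class
    )
    ttps, tmin, fallback = ttp_min(slice_curves, config, whole_roi_curve)
    evidence["whole_roi_class"] = whole_class
    evidence["heterogeneous_decreasing"] = heterogeneous_decreasing
    return KineticResult(
        curve_class=tumour_class,
        per_slice_classes=tuple(slice_classes),
        slice_indices=tuple(z if z is not None else -1 for z in zs),
        ttp_per_slice=tuple(ttps),
        ttp_min=tmin,
        ttp_min_fallback=fallback,
        evidence=evidence,
    )
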