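"""Synthetic phantoms and cohorts with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: ellipsoidal lesions of specified TBR in a noisy homogeneous
background (static segmentation and TBR metrics), dynamic series built from
the three kinetic families (TAC classification and TTP), companion masks
constructed to hit a target Dice (overlap analysis), and stratified patient
cohorts with exact category counts (statistics layer).

Generators are fully deterministic under their seed, and noiseless specs
make every stage exactly invertible — segmentation, kinetic class, TTP and
Dice all equal the generator's ground truth.

No anatomical or physical realism is attempted (no scatter, attenuation or
point-spread modelling); lesions are hard-edged ellipsoids because the
ground-truth voxel set must be unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .cohort_stats import CURVE_CLASSES, PatientRecord
from .imaging_io import DynamicSeries, FrameSchedule, Mask, VolumeGrid
from .static_quant import _ellipsoid_mask


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


# ---------------------------------------------------------------------------
# Static phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: centre voxel, mm semi-axes, TBR, internal noise."""

    centre: tuple[int, int, int]
    semi_axes_mm: tuple[float, float, float]
    tbr: float
    intra_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tbr <= 0:
            raise ValueError("lesion TBR must be > 0")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """A noisy homogeneous brain background with ellipsoidal lesions."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 1.0
    background_sd: float = 0.05
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec(centre=(32, 24, 12), semi_axes_mm=(10.0, 8.0, 8.0), tbr=2.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


def make_static_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, Mask, Mask]:
    """Build a static SUV phantom.

    Returns ``(volume, lesion_mask, background_roi)``. Lesion voxels are set
    to ``tbr x background_mean`` plus intra-lesion Gaussian noise; the rest
    of the grid is background with its own noise. The background ROI is an
    ellipsoid mirrored contralaterally (across the mid-x plane) from the
    first lesion, with any lesion voxels excluded.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    affine = _affine(spacing)

    values = np.full(shape, spec.background_mean, dtype=np.float64)
    if spec.background_sd > 0:
        values += rng.normal(0.0, spec.background_sd, size=shape)

    lesion_total = np.zeros(shape, dtype=np.uint8)
    for les in spec.lesions:
        _check_lesion_in_grid(les, shape, spacing)
        lm = _ellipsoid_mask(shape, les.centre, les.semi_axes_mm, spacing).astype(bool)
        values[lm] = les.tbr * spec.background_mean
        if les.intra_sd > 0:
            values[lm] += rng.normal(0.0, les.intra_sd, size=int(lm.sum()))
        lesion_total[lm] = 1

    values = np.clip(values, 0.0, None)
    volume = VolumeGrid(values, affine)
    lesion_mask = Mask(lesion_total, affine, label="pet_segmentation")
    background_roi = _background_roi(spec, shape, spacing, affine, lesion_total)
    return volume, lesion_mask, background_roi


def _check_lesion_in_grid(les: LesionSpec, shape, spacing) -> None:
    for ax in range(3):
        half_vox = les.semi_axes_mm[ax] / spacing[ax]
        if les.centre[ax] - half_vox < 0 or les.centre[ax] + half_vox > shape[ax] - 1:
            raise ValueError(f"lesion at {les.centre} extends outside grid {shape}")


def _background_roi(spec, shape, spacing, affine, lesion_total) -> Mask:
    if spec.lesions:
        first = spec.lesions[0]
        centre = (shape[0] - 1 - first.centre[0], first.centre[1], first.centre[2])
        semi = first.semi_axes_mm
    else:
        centre = tuple(s // 2 for s in shape)
        semi = tuple(0.25 * s * sp for s, sp in zip(shape, spacing))
    roi = _ellipsoid_mask(shape, centre, semi, spacing)
    roi[lesion_total > 0] = 0
    return Mask(roi, affine, label="background_roi")


# ---------------------------------------------------------------------------
# Dynamic phantoms and TAC families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DynamicSpec:
    """Parameters of a synthetic time–activity curve family.

    ``curve_family`` selects the kinetic shape; ``peak_time_min`` (snapped to
    the nearest frame mid-time) positions the peak for the decreasing and
    stable families; ``plateau_level`` scales the increasing family;
    ``noise_sd_rel`` is per-frame Gaussian noise relative to the peak value;
    ``end_fraction`` is the decreasing family's terminal level (a decline of
    at least 15% by scan end).
    """

    schedule: FrameSchedule
    curve_family: str
    peak_time_min: Optional[float] = None
    plateau_level: float = 0.95
    noise_sd_rel: float = 0.0
    end_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve_family not in CURVE_CLASSES:
            raise ValueError(f"unknown curve family {self.curve_family!r}")
        if not 0 < self.plateau_level < 1:
            raise ValueError("plateau_level must be in (0, 1)")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if not 0 < self.end_fraction <= 0.85:
            raise ValueError("end_fraction must be in (0, 0.85] (>= 15% decline)")
        if self.peak_time_min is not None:
            lo, hi = self.schedule.span
            if not (lo <= self.peak_time_min <= hi):
                raise ValueError("peak_time_min outside schedule span")


#: Fluctuation profile of the stable family, in units of 1% of peak. The
#: shape is nearly flat (within ~1% of peak) with the final frame set 4%
#: below the peak: far enough down that frame-noise rarely relocates the
#: maximum to the last frame (which would read as a continuous rise), yet
#: well inside the +/-10% stability band so the late change never reads as
#: a decline.
_STABLE_WOBBLE = np.array([1.2, 0.8, 1.1, 0.9, 1.0, 1.15])
_STABLE_LAST_FRAME = 0.965


def base_curve(spec: DynamicSpec) -> tuple[np.ndarray, str, float]:
    """Noiseless family curve normalized to peak 1.0.

    Returns ``(values, true_class, true_ttp_min)`` where the true TTP is the
    mid-time of the peak frame (last frame for the increasing family).
    """
    mid = spec.schedule.mid_times
    n = len(mid)
    if spec.curve_family == "increasing":
        # saturating rise reaching plateau_level of the asymptote by scan end
        t_end = float(mid[-1])
        tau = -t_end / np.log(1.0 - spec.plateau_level)
        vals = 1.0 - np.exp(-mid / tau)
        vals /= vals.max()
        return vals, "increasing", float(mid[-1])

    peak_time = spec.peak_time_min
    if peak_time is None:
        peak_time = 12.5 if spec.curve_family == "decreasing" else float(mid[0])
    p = int(np.argmin(np.abs(mid - peak_time)))

    if spec.curve_family == "decreasing":
        vals = np.empty(n)
        # linear rise from 0.6 to the peak, then linear decline to end_fraction
        if p > 0:
            vals[: p + 1] = np.linspace(0.6, 1.0, p + 1)
        else:
            vals[0] = 1.0
        if p < n - 1:
            vals[p:] = 1.0 + (spec.end_fraction - 1.0) * (mid[p:] - mid[p]) / (
                mid[-1] - mid[p]
            )
        return vals, "decreasing", float(mid[p])

    # stable: designated peak frame at 1.0, others wobbling ~1% below,
    # final frame 4% below (see _STABLE_WOBBLE note)
    if p == n - 1:
        raise ValueError("stable family cannot peak at the final frame")
    vals = 1.0 - 0.01 * np.resize(_STABLE_WOBBLE, n)
    vals[-1] = _STABLE_LAST_FRAME
    vals[p] = 1.0
    return vals, "stable", float(mid[p])


def make_tac(spec: DynamicSpec, rng: Optional[np.random.Generator] = None) -> tuple[np.ndarray, str, float]:
    """One synthetic TAC (values per frame), its true class and true TTP.

    Noise is i.i.d. Gaussian per frame with sd ``noise_sd_rel`` x peak.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    vals, cls, ttp = base_curve(spec)
    if spec.noise_sd_rel > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd_rel, size=vals.shape)
    return vals, cls, ttp


def make_dynamic_phantom(
    phantom: PhantomSpec, dyn: DynamicSpec
) -> tuple[DynamicSeries, str, float]:
    """4-D phantom whose lesion voxels follow the family curve.

    The lesion's peak SUV is ``tbr x background_mean``; background voxels are
    flat in time (plus per-frame noise of ``background_sd``). Returns the
    series with the ground-truth class and TTP labels.
    """
    rng = np.random.default_rng(dyn.seed)
    shape = tuple(phantom.grid_shape)
    spacing = np.asarray(phantom.spacing, dtype=float)
    affine = _affine(spacing)
    n_frames = len(dyn.schedule)
    base, cls, ttp = base_curve(dyn)

    data = np.full(shape + (n_frames,), phantom.background_mean, dtype=np.float64)
    if phantom.background_sd > 0:
        data += rng.normal(0.0, phantom.background_sd, size=data.shape)

    for les in phantom.lesions:
        _check_lesion_in_grid(les, shape, spacing)
        lm = _ellipsoid_mask(shape, les.centre, les.semi_axes_mm, spacing).astype(bool)
        peak_suv = les.tbr * phantom.background_mean
        curve = peak_suv * base
        block = np.broadcast_to(curve, (int(lm.sum()), n_frames)).copy()
        if dyn.noise_sd_rel > 0:
            block += rng.normal(0.0, dyn.noise_sd_rel * peak_suv, size=block.shape)
        data[lm, :] = block

    data = np.clip(data, 0.0, None)
    return DynamicSeries(data, affine, dyn.schedule), cls, ttp


# ---------------------------------------------------------------------------
# Mask pairs with a target Dice
# ---------------------------------------------------------------------------


def make_mask_pair(reference: Mask, target_dice: float, seed: int = 0) -> Mask:
    """Companion mask whose Dice against ``reference`` hits the target.

    Construction: the companion keeps the ``k = round(d·n)`` reference voxels
    closest to the reference centroid and adds the ``n − k`` nearest outside
    voxels, so both masks have ``n`` voxels and Dice is exactly ``k/n``
    (within 0.5/n of the target, well inside the ±0.02 contract for any
    reference of ≥ 25 voxels). Target 1 returns a copy; target 0 a disjoint
    translate of the reference. The seed only breaks distance ties.
    """
    if not 0.0 <= target_dice <= 1.0:
        raise ValueError("target_dice must be in [0, 1]")
    if reference.is_empty:
        raise ValueError("reference mask is empty")
    n = reference.n_voxels
    if target_dice == 1.0:
        return Mask(reference.values.copy(), reference.affine, label=reference.label)
    if target_dice == 0.0:
        return _disjoint_translate(reference)

    k = int(round(target_dice * n))
    if abs(k / n - target_dice) > 0.02:
        raise ValueError(
            f"target Dice {target_dice} unreachable at ±0.02 with a "
            f"{n}-voxel reference"
        )
    rng = np.random.default_rng(seed)
    idx = reference.indices().astype(float)
    centroid = idx.mean(axis=0)
    d_in = np.linalg.norm(idx - centroid, axis=1) + rng.uniform(0, 1e-9, size=len(idx))
    keep = reference.indices()[np.argsort(d_in)[:k]]

    outside = reference.values == 0
    d_out = ndimage.distance_transform_edt(reference.values == 0)
    cand = np.argwhere(outside)
    d_cand = d_out[outside] + rng.uniform(0, 1e-9, size=len(cand))
    need = n - k
    if need > len(cand):
        raise ValueError("grid too small to place the companion mask")
    add = cand[np.argsort(d_cand)[:need]]

    out = np.zeros(reference.shape, dtype=np.uint8)
    sel = np.vstack([keep, add]) if need else keep
    out[tuple(sel.T)] = 1
    return Mask(out, reference.affine, label=reference.label)


def _disjoint_translate(reference: Mask) -> Mask:
    idx = reference.indices()
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    extent = hi - lo + 1
    for ax in range(3):
        for sign in (1, -1):
            shift = np.zeros(3, dtype=int)
            shift[ax] = sign * (extent[ax] + 2)
            moved = idx + shift
            if np.all(moved >= 0) and np.all(moved < np.asarray(reference.shape)):
                out = np.zeros(reference.shape, dtype=np.uint8)
                out[tuple(moved.T)] = 1
                if not np.any(out & reference.values):
                    return Mask(out, reference.affine, label=reference.label)
    raise ValueError("no room in the grid for a disjoint companion mask")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumSpec:
    """Exact per-stratum composition of a synthetic cohort.

    All category counts are exact (assigned by construction, not sampled),
    so cross-tabulations of the generated cohort reproduce the specified
    tables deterministically; only the continuous metrics (TBR, volumes,
    Dice) are drawn from the stratum's distributions.
    """

    histology: str
    who_grade: int
    n: int
    n_ce: int
    n_pet_positive: int
    n_dynamic: int
    kinetic_counts: dict  # class -> count, summing to n_dynamic
    ttp_counts: dict  # TTP_min level (min) -> count, summing to n_dynamic
    tbr_pos_median: float = 2.0
    tbr_sigma: float = 0.35
    dice_flair_median: float = 0.5
    dice_ce_median: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.n_ce <= self.n and 0 <= self.n_pet_positive <= self.n):
            raise ValueError("category counts exceed stratum size")
        if self.n_dynamic > self.n_pet_positive:
            raise ValueError("dynamic scans only exist for PET-positive cases")
        if sum(self.kinetic_counts.values()) != self.n_dynamic:
            raise ValueError("kinetic_counts must sum to n_dynamic")
        if sum(self.ttp_counts.values()) != self.n_dynamic:
            raise ValueError("ttp_counts must sum to n_dynamic")
        if any(c not in CURVE_CLASSES for c in self.kinetic_counts):
            raise ValueError("unknown kinetic class in kinetic_counts")


@dataclass(frozen=True)
class CohortSpec:
    strata: tuple[StratumSpec, ...]
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return sum(s.n for s in self.strata)


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a stratified cohort with exact category counts.

    Within each stratum, PET positivity, CE presence, dynamic availability,
    kinetic class and TTP_min level are assigned with exactly the specified
    counts (decreasing curves receive the earliest TTP levels, matching the
    early-peak behaviour of aggressive tumours); TBR and Dice values are
    drawn per stratum. Identical spec + seed gives identical records.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    pid = 0
    for st in spec.strata:
        records.extend(_make_stratum(st, rng, start_id=pid))
        pid += st.n
    return records


def _make_stratum(st: StratumSpec, rng: np.random.Generator, start_id: int) -> list[PatientRecord]:
    pos = [True] * st.n_pet_positive + [False] * (st.n - st.n_pet_positive)
    dyn = [i < st.n_dynamic for i in range(st.n)]  # dynamic cases are positive by contract

    classes: list[Optional[str]] = []
    for cls in ("decreasing", "stable", "increasing"):
        classes.extend([cls] * st.kinetic_counts.get(cls, 0))
    ttps = sorted(
        (float(level) for level, c in st.ttp_counts.items() for _ in range(int(c)))
    )
    # earliest peaks go to the decreasing curves
    ce_idx = set(rng.choice(st.n, size=st.n_ce, replace=False).tolist())

    recs = []
    for i in range(st.n):
        is_pos = pos[i]
        is_dyn = dyn[i]
        if is_pos:
            tbr_max = max(1.6, float(np.exp(rng.normal(np.log(st.tbr_pos_median), st.tbr_sigma))))
            tbr_mean = 1.0 + (tbr_max - 1.0) * rng.uniform(0.5, 0.8)
            volume = float(np.exp(rng.normal(np.log(8.0), 0.8)))
            dice_flair = float(np.clip(rng.normal(st.dice_flair_median, 0.08), 0.02, 0.99))
        else:
            tbr_max = float(rng.uniform(1.0, 1.55))
            tbr_mean = None
            volume = 0.0
            dice_flair = None
        ce = i in ce_idx
        dice_ce = (
            float(np.clip(rng.normal(st.dice_ce_median, 0.08), 0.01, 0.95))
            if (ce and is_pos)
            else None
        )
        recs.append(
            PatientRecord(
                patient_id=f"P{start_id + i:04d}",
                histology=st.histology,
                who_grade=st.who_grade,
                ce_present=ce,
                pet_positive=is_pos,
                tbr_max=tbr_max,
                tbr_mean=tbr_mean,
                pet_volume_ml=volume,
                curve_class=classes[i] if is_dyn else None,
                ttp_min=ttps[i] if is_dyn else None,
                dice_flair=dice_flair,
                dice_ce=dice_ce,
            )
        )
    return recs


def make_patient_dataset(
    outdir,
    patient_id: str,
    histology: str,
    who_grade: int,
    lesion_tbr: float = 2.5,
    curve_family: Optional[str] = None,
    dice_flair: float = 0.6,
    dice_ce: Optional[float] = None,
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    seed: int = 0,
    noiseless: bool = True,
) -> tuple[dict, dict]:
    """Write one synthetic patient's NIfTI files plus ground truth.

    Builds a static phantom (and a dynamic series when ``curve_family`` is
    given, with the static volume taken from the 20–40 min summation so both
    views are consistent), a background ROI, and FLAIR/CE masks constructed
    against the true lesion at the requested Dice targets. Returns
    ``(paths, truth)``: the file paths for a pipeline manifest entry and the
    generator's ground-truth labels.
    """
    from pathlib import Path

    from .imaging_io import write_dynamic, write_mask, write_volume
    from .static_quant import summation_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    centre = (grid_shape[0] * 2 // 3, grid_shape[1] // 2, grid_shape[2] // 2)
    phantom = PhantomSpec(
        grid_shape=grid_shape,
        spacing=(2.0, 2.0, 2.0),
        background_mean=1.0,
        background_sd=0.0 if noiseless else 0.05,
        lesions=(LesionSpec(centre=centre, semi_axes_mm=(10.0, 8.0, 8.0), tbr=lesion_tbr),),
        seed=seed,
    )
    volume, lesion, bg_roi = make_static_phantom(phantom)
    paths = {"background_mask": str(outdir / f"{patient_id}_bg.nii.gz")}
    write_mask(bg_roi, paths["background_mask"])

    truth: dict = {
        "pet_positive": lesion_tbr >= 1.6,
        "curve_class": None,
        "ttp_min": None,
        "dice_flair": dice_flair if lesion_tbr >= 1.6 else None,
        "dice_ce": dice_ce if lesion_tbr >= 1.6 else None,
        "lesion_voxels": lesion.n_voxels,
    }

    if curve_family is not None:
        dyn = DynamicSpec(
            schedule=FrameSchedule(((0, 5), (5, 10), (10, 15), (15, 20), (20, 30), (30, 40))),
            curve_family=curve_family,
            noise_sd_rel=0.0 if noiseless else 0.02,
            seed=seed,
        )
        series, cls, ttp = make_dynamic_phantom(phantom, dyn)
        paths["dynamic"] = str(outdir / f"{patient_id}_dyn.nii.gz")
        paths["schedule"] = str(outdir / f"{patient_id}_schedule.json")
        write_dynamic(series, paths["dynamic"])
        dyn.schedule.to_json(paths["schedule"])
        pet = summation_image(series, 20, 40)
        truth["curve_class"] = cls
        truth["ttp_min"] = ttp
    else:
        pet = volume
    paths["pet"] = str(outdir / f"{patient_id}_pet.nii.gz")
    write_volume(pet, paths["pet"])

    flair = make_mask_pair(lesion, dice_flair, seed=seed)
    flair = Mask(flair.values, flair.affine, label="flair")
    paths["flair"] = str(outdir / f"{patient_id}_flair.nii.gz")
    write_mask(flair, paths["flair"])
    if dice_ce is not None:
        ce = make_mask_pair(lesion, dice_ce, seed=seed + 1)
        ce = Mask(ce.values, ce.affine, label="ce")
        paths["ce"] = str(outdir / f"{patient_id}_ce.nii.gz")
        write_mask(ce, paths["ce"])
    return paths, truth


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Default study conditions: a 147-patient IDH-mutant glioma cohort.

    Stratum sizes, contrast-enhancement and PET-positivity counts, dynamic
    availability and kinetic/TTP_min class frequencies follow the reported
    clinical distribution for astrocytoma (WHO grades 2–4) and
    oligodendroglioma (grades 2–3); the joint histology x grade x kinetic
    assignment is chosen to reproduce both the per-grade margin
    (41,13,5 / 13,9,4 / 2,0,4) and the per-histology margin
    (24,5,4 / 32,17,9) exactly.
    """
    strata = (
        StratumSpec(
            "astrocytoma", 2, n=49, n_ce=10, n_pet_positive=16, n_dynamic=14,
            kinetic_counts={"increasing": 12, "stable": 2, "decreasing": 0},
            ttp_counts={35.0: 10, 25.0: 3, 17.5: 1},
            tbr_pos_median=1.9, dice_flair_median=0.33, dice_ce_median=0.14,
        ),
        StratumSpec(
            "astrocytoma", 3, n=21, n_ce=6, n_pet_positive=13, n_dynamic=13,
            kinetic_counts={"increasing": 10, "stable": 3, "decreasing": 0},
            ttp_counts={35.0: 9, 25.0: 3, 17.5: 1},
            tbr_pos_median=2.0, dice_flair_median=0.31, dice_ce_median=0.21,
        ),
        StratumSpec(
            "astrocytoma", 4, n=9, n_ce=8, n_pet_positive=6, n_dynamic=6,
            kinetic_counts={"increasing": 2, "stable": 0, "decreasing": 4},
            ttp_counts={12.5: 4, 17.5: 1, 35.0: 1},
            tbr_pos_median=2.7, dice_flair_median=0.71, dice_ce_median=0.61,
        ),
        StratumSpec(
            "oligodendroglioma", 2, n=52, n_ce=10, n_pet_positive=49, n_dynamic=45,
            kinetic_counts={"increasing": 29, "stable": 11, "decreasing": 5},
            ttp_counts={35.0: 30, 25.0: 10, 17.5: 5},
            tbr_pos_median=2.24, dice_flair_median=0.63, dice_ce_median=0.08,
        ),
        StratumSpec(
            "oligodendroglioma", 3, n=16, n_ce=10, n_pet_positive=13, n_dynamic=13,
            kinetic_counts={"increasing": 3, "stable": 6, "decreasing": 4},
            ttp_counts={25.0: 8, 35.0: 4, 17.5: 1},
            tbr_pos_median=3.1, dice_flair_median=0.77, dice_ce_median=0.20,
        ),
    )
    return CohortSpec(strata=strata, seed=seed)
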