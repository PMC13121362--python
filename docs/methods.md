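# Methods

This note documents the quantitative model implemented by `fetquant`, the
choices made where the clinical methodology leaves details open, and what
the synthetic validation does and does not establish.

## Spatial data model

Volumes are 3-D standardized-uptake-value (SUV) fields with a NIfTI
voxel-to-world affine; voxel indices are 0-based in (x, y, z) order with z
the axial slice axis, and the voxel volume in ml is the product of the mm
spacings / 1000. SUV is body-weight normalized and unitless. Small negative
voxels, a common artefact of iterative reconstruction, are clamped to zero
on load with the count logged rather than rejected. Masks are strictly
binary and must share their reference volume's grid exactly: a mismatch is
a hard error, never a silent resample, because interpolating a mask changes
both Dice and TBR in uncontrolled ways. Registration is consumed, not
computed — inputs are declared pre-registered, and an optional user-supplied
world-space affine can be applied to a mask with nearest-neighbour
resampling (order-0, so binaryness is preserved by construction).

## Static quantification

The background estimate is the mean SUV over a user-supplied background ROI
(≥ 100 voxels by default) in the healthy contralateral hemisphere; a helper
builds a mirrored contralateral ellipsoid from a given centre, since
published ROI geometries for this step are not standardized. The
segmentation threshold is `threshold_factor × background mean` with the
clinical default factor 1.6. All supra-threshold voxels are candidate
tumour; connected components (26-neighbourhood) smaller than 0.1 ml are
discarded as reconstruction noise, and an optional seed point restricts the
result to the seed's (or nearest) component as a reproducible stand-in for
semiautomatic operator selection. An empty mask is a valid outcome — a
PET-negative tumour.

`TBR_max` and `TBR_mean` divide SUV_max / SUV_mean over the segmented
voxels by the background mean; positivity is the closed boundary
`TBR_max ≥ 1.6` (PET-RANO 1.0). For an empty segmentation the segment
metrics are absent and `TBR_max` falls back to the maximum SUV within a
search region (whole volume by default) over background, so PET-negative
cases still carry a measurable `TBR_max` — this matches the convention of
reporting TBR values from 1.0 upward for negative tumours. Multifocal
lesions are merged into one PET volume (all surviving components) unless a
seed point selects one focus.

Summation images are duration-weighted means of complete frames; window
boundaries must coincide with frame boundaries (no partial-frame
interpolation). The standard windows are 20–40 min (static-equivalent) and
10–30 min (kinetic ROI definition).

## Dynamic kinetics

The tumour ROI is a volumetric 90% isocontour of the maximum on the
10–30 min summation image (applied per-volume, not per-slice), restricted
to a search mask when one is given; it is non-empty by construction. The
same ROI is applied to every frame to extract TACs; slice-wise TACs skip
slices contributing fewer than 3 ROI voxels, which are noise-dominated.

The three clinically used curve classes are qualitative in practice; they
are operationalized deterministically. With s the frame means, p the
earliest index attaining the maximum, band = 0.10:

1. p at the final frame → **increasing** (continuous rise);
2. `Δ = (s_last − s_p)/s_p ≥ −band` and `R = (s_p − s_early)/s_p > band`
   → **increasing** (rise then plateau), where s_early is the mean of
   frames with mid-time ≤ 5 min;
3. `Δ < −0.10` with no post-peak step rising more than `band × s_p`
   → **decreasing** (peak then constant decline);
4. all values within `± band × s_p` of the peak → **stable**;
5. otherwise the sign of the least-squares slope over frames with mid-time
   past 5 min decides (positive → increasing, negative → decreasing,
   zero → stable).

All thresholds live in `KineticConfig`. Ties at the maximum resolve to the
earliest frame ("initial peak" reading), which makes TTP deterministic. TTP
is the mid-time of that frame; TTP_min is the smallest TTP shared by at
least two adjacent axial slices (literal equality; skipped slices break
adjacency), falling back to the whole-ROI TTP with a flag when no value
repeats — the fallback keeps the statistic total without inventing
adjacent support. The tumour-level class is decreasing when either the
whole-ROI curve or at least two adjacent slices classify decreasing
(homogeneous or heterogeneous decline); otherwise the whole-ROI class.

On the default 0–40 min schedule (0–5, 5–10, 10–15, 15–20, 20–30,
30–40 min — frame binning is scanner-protocol dependent, so the schedule is
a required input and this is only a default), achievable TTP values are
exactly {2.5, 7.5, 12.5, 17.5, 25, 35} min, the levels at which TTP_min is
reported clinically.

## Spatial overlap

Dice is computed on voxel counts (identical grids are enforced upstream, so
counts and ml volumes are proportional) and reported in ml as well. A
comparison is evaluable only when both masks are non-empty; empty-vs-empty
is not-evaluable rather than 0 or 1, mirroring the clinical exclusion of
PET-negative or MRI-silent cases from overlap analysis. An absent CE mask
yields a non-evaluable PET–CE entry with the reason recorded.

## Cohort statistics

Pearson χ² is computed without continuity correction on all tables
including 2×2 (required to reproduce the reported statistics from integer
tables); expected counts < 5 set a warning flag. Fisher's exact test sums
hypergeometric probabilities ≤ the observed table's. Mann–Whitney U uses
midranks and reports `U = min(U_x, U_y)` — the most common reporting
convention; p-values are exact for combined n ≤ 25 without ties and use the
tie-corrected normal approximation (no continuity correction, as SPSS
reports it) otherwise. Kruskal–Wallis applies the tie correction with the
χ²_{k−1} approximation; for the degenerate all-identical-constants input it
returns H = 0, p = 1. Cohen's κ uses marginal-product chance agreement; the
reported p-value is the large-sample normal test of κ = 0 with the Fleiss
null standard error. No multiplicity correction is applied anywhere, and
missing values are excluded per analysis with the exclusion count always
reported alongside the denominator.

## Synthetic data: what it emulates and what it does not

The generators are designed so that ground truth is unambiguous, not so
that images look realistic. Lesions are hard-edged ellipsoids on a
homogeneous background with independent Gaussian voxel noise; there is no
scatter, attenuation, partial-volume or point-spread modelling, no
anatomical template, and no correlated noise. Passing tests therefore
establish the correctness of the measurement chain (segmentation, TAC
extraction, classification, Dice, statistics) on data satisfying the
pipeline's assumptions — they do not establish robustness to the texture,
heterogeneity and registration error of clinical scans.

Dynamic families, normalized to peak 1.0: *increasing* is a saturating
exponential reaching 95% of its asymptote by scan end (monotone, peak at
the final frame); *decreasing* rises linearly to the peak frame then
declines linearly to 75% of peak by scan end (≥ 15% decline); *stable* is
nearly flat (~1% wobble) with its designated peak frame at 1.0 and the
final frame at 0.965 of peak. The stable shape is a deliberate compromise:
under the fixed classification thresholds, frame noise on a flat curve can
relocate the maximum to the final frame (reading as a continuous rise),
push the late change below −10% (reading as a decline), or inflate the
peak until the band check fails. Setting the final frame ≈ 3.5% below the
peak balances these channels and gives ≈ 96% expected recovery per class
at 2% frame noise — the residual error is a property of the deterministic
rule at that noise level, not of the implementation.

Mask pairs with a target Dice are built by exact count: the companion keeps
the `round(d·n)` reference voxels nearest the centroid and adds the nearest
outside voxels up to equal size, so Dice is exactly `k/n` (within `0.5/n`
of the target); the seed only breaks distance ties. Cohorts use exact
category counts per stratum (assignment, not sampling), which makes
cross-tabulations of the generated cohort reproduce the specified tables
deterministically; only continuous metrics (TBR, volumes, Dice values) are
drawn from per-stratum distributions. The default 147-patient cohort
encodes the reported stratum sizes, positivity, contrast-enhancement,
dynamic-availability and kinetic/TTP_min frequencies; since only the
per-grade and per-histology kinetic margins are reported, the joint
histology × grade × class assignment is one feasible completion that
reproduces both margins exactly.

## Problem sizes and numerical choices

Validation runs use grids up to 64³ with 2 mm isotropic voxels, 50 random
phantoms for the segmentation oracle, 200 curves per kinetic family, 1000
random mask pairs for the Dice property suite, 2000 null simulations for
the Kruskal–Wallis calibration, and a 30-patient noiseless cohort for the
end-to-end round trip — sizes at which the exhaustive oracles (per-voxel
scans, enumeration of all group assignments for the exact tests) remain
tractable while the statistics are stable. Affine comparisons use an
absolute tolerance of 1e-4 mm; summation windows align to frame boundaries
within 1e-9 min; all random generation flows through seeded
`numpy.random.Generator` instances, and identical seed + spec is
bit-identical everywhere.

## Known limitations

Partial-volume effects, motion, and input-function-based compartmental
modelling are out of scope, as are DICOM assembly, registration estimation
and scanner-specific SUV calibration. The Mann–Whitney U reporting
convention and the exact provenance of TBR_max for PET-negative tumours
(fixed search VOI vs. whole-brain maximum) cannot be pinned down from
published descriptions; both are configurable, with the defaults stated
above.
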