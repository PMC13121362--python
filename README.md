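# fetquant

Quantitative analysis of [¹⁸F]FET PET and MRI in IDH-mutant glioma.

Amino-acid PET with O-(2-[¹⁸F]fluoroethyl)-L-tyrosine ([¹⁸F]FET) is used in
neuro-oncology to delineate metabolically active tumour beyond what
contrast-enhanced MRI shows. `fetquant` implements the standard quantitative
workflow for this setting as a tested, reusable pipeline for researchers who
need reproducible PET/MRI biomarkers across a patient cohort:

* **Static quantification** — the mean SUV of a healthy contralateral
  background region B̄ defines the segmentation threshold `1.6 × B̄`; the
  supra-threshold tumour volume yields `TBR_max = SUV_max / B̄` and
  `TBR_mean = SUV_mean / B̄`, the PET volume in ml, and PET-RANO 1.0
  positivity (`TBR_max ≥ 1.6`).
* **Dynamic kinetics** — a 90% isocontour ROI on the 10–30 min summation
  image, applied to all frames, gives time–activity curves (TACs) that are
  classified as *increasing*, *stable*, or *decreasing*; time-to-peak (TTP)
  per axial slice yields TTP_min, the shortest TTP shared by at least two
  consecutive slices.
* **Spatial overlap** — Dice coefficient
  `DICE = 2|V_PET ∩ V_MRI| / (|V_PET| + |V_MRI|)` between the PET
  segmentation and FLAIR / contrast-enhancing MRI lesion masks, computed
  only when both lesions are segmentable.
* **Cohort statistics** — median (range) and n (%) summaries stratified by
  histology (astrocytoma vs. oligodendroglioma) and CNS WHO grade, with
  Pearson χ² (no continuity correction), Fisher's exact test,
  Mann–Whitney U, Kruskal–Wallis H and Cohen's κ; two-tailed p < 0.05, no
  multiple-testing correction.
* **Synthetic data** — phantoms and cohorts with known ground truth
  (ellipsoidal lesions of specified TBR, the three kinetic families, mask
  pairs at a target Dice, stratified cohorts with exact category counts), so
  every stage is testable end-to-end without patient data.

Inputs are pre-registered NIfTI volumes on a common grid (static SUV volume
or 4-D dynamic series plus frame schedule, binary MRI lesion masks, a
background ROI mask) and a per-patient CSV at the cohort level. Registration
is consumed, never estimated; a user-supplied affine can be applied to a
mask with nearest-neighbour resampling.

## Worked example

```python
import fetquant as fq

# a noiseless phantom: background SUV 1.0, one ellipsoidal lesion at TBR 2.5
spec = fq.PhantomSpec(background_sd=0.0)
volume, lesion, bg_roi = fq.make_static_phantom(spec)

background = fq.estimate_background(volume, bg_roi)
segmentation, threshold = fq.segment_lesion(volume, background)
metrics = fq.compute_uptake_metrics(volume, segmentation, background,
                                    threshold_suv=threshold)
print(f"threshold SUV {threshold:.2f}  TBR_max {metrics.tbr_max:.2f}  "
      f"volume {metrics.pet_volume_ml:.2f} ml  positive={metrics.pet_positive}")
# threshold SUV 1.60  TBR_max 2.50  volume 2.78 ml  positive=True
```

The threshold is 1.6 × the background mean (1.0), the lesion reads at
TBR 2.5 and is therefore PET-positive; the segmented volume is the voxel
count times the voxel volume. The same phantom with a decreasing dynamic
family classifies accordingly:

```python
dyn = fq.DynamicSpec(schedule=fq.DEFAULT_SCHEDULE, curve_family="decreasing",
                     peak_time_min=12.5)
series, true_class, true_ttp = fq.make_dynamic_phantom(spec, dyn)
roi = fq.isocontour_roi(fq.summation_image(series, 10, 30), 0.9)
result = fq.classify_tumour_kinetics(fq.extract_slice_tacs(series, roi),
                                     fq.extract_tac(series, roi))
print(result.curve_class, result.ttp_min)
# decreasing 12.5
```

An early peak (12.5 min) with a constant decline is the kinetic signature
associated with higher-grade disease, and TTP_min lands on the frame
mid-time of the generator's peak.

The same operations are exposed as a CLI (`fetquant static`, `dynamic`,
`dice`, `cohort`, `simulate`, `run`); `fetquant run --config config.yaml`
executes the full per-patient chain plus cohort statistics from a YAML
manifest with continue-on-error batch semantics and provenance
(config hash, input checksums) in every report.

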