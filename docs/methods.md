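# Methods

This note records the model behind each module, the default parameters
with their rationale, the numerical choices that matter, and the known
limitations of the synthetic data.

## 1. The ECV model

The extracellular volume fraction of myocardium is estimated from the
attenuation change between a pre-contrast and a delayed (equilibrium)
contrast phase:

```
ECV = (dHU_m / dHU_b) * (1 - Hct)
```

where `dHU_m` is the mean attenuation change of a myocardial segment,
`dHU_b` the change in the left-ventricular blood pool, and `Hct` the
hematocrit. The rationale: at contrast equilibrium the agent
concentration ratio between tissue interstitium and blood plasma equals
the ratio of their distribution volumes, and `1 - Hct` converts from
whole blood to plasma.

Per-segment readout uses the AHA 16-segment model; segments classified
as ischemic scar are excluded and the patient ECV is the unweighted mean
of the remaining segments (scar would inflate the diffuse-fibrosis
estimate with focal pathology).

## 2. Phantom generator

The left ventricle is a truncated half-ellipsoid shell on a
96×96×96 grid at 1 mm isotropic spacing:

| parameter | default | rationale |
|---|---|---|
| endo / epi short-axis radius | 16 / 26 mm | 10 mm wall, adult LV scale |
| long-axis extent | 52 mm | base plane to apex tip |
| pre-contrast HU (blood, myo) | 40, 40 | iso-intense, as unenhanced CT |
| background | −100 HU | lung/fat surrogate |
| blood-pool enhancement `dHU_b` | 100 HU | delayed-phase scale |
| hematocrit | 0.40 | mid-normal |
| true per-segment ECV | 0.22…0.32 linear | spans normal-to-elevated |
| noise SD | 10 HU | low-dose delayed acquisition |
| texture SD / correlation | 15 HU / 4 mm | see below |

The delayed phase is derived by *inverting* the ECV equation: each
segment's wall voxels gain `ECV_seg * dHU_b / (1 − Hct)`; the apex cap
(unlabelled in the 16-segment model) gets the apical-segment mean.
Optional lesions add `delta_hu` inside a normalized-transmural-depth
band of one segment (subendocardial: depth from 0; midwall: strictly
positive `depth_min`).

**Texture.** Piecewise-constant tissue makes the tangential component of
any deformation unidentifiable for every registration metric. A smooth,
seeded intensity texture (Gaussian-filtered white noise, SD 15 HU,
4 mm correlation length) is therefore added inside the epicardial solid
*before* the delayed phase is derived — both phases carry the identical
texture, so it cancels in an aligned subtraction and noiseless ECV
recovery stays exact to machine precision.

**Misalignment.** The delayed phase can be warped by a rigid motion
(Euler angles + translation about the LV centre) composed with a smooth
sinusoidal displacement field (period 64 mm). The generator stores the
exact resampling transform as ground truth, oriented so that `register`
recovers the physical motion parameters directly.

Other generators: a gamma-variate arterial input with tissue curves
whose maximum upslope encodes per-segment MBF (section 4); an
unenhanced 1×1×3 mm calcium volume whose plaques are painted as
nearest-pixel disks at a requested area and peak HU, with background
clipped safely below the 130 HU scoring threshold; and a two-group
cohort table with configurable means/SDs/prevalences and a requested
within-group ECV–LAVI correlation.

Problem sizes (96³ grid, 200-cohort simulations, 2000-replicate
calibration) are this package's own choices, balancing statistical
resolution against a single-CPU test budget.

## 3. Registration and subtraction

`register(moving, fixed, mode, method)` estimates the transform mapping
fixed-grid points into the moving volume (the resampling convention).

* **Rigid stage** — Euler3D, mean-squared-difference metric on demeaned
  images (invariant to a global HU offset), 3-level multi-resolution
  pyramid, regular-step gradient descent with physical-shift parameter
  scaling. Recovers applied translations/rotations to well under
  0.1 mm / 0.1°.
* **Deformable, `method="bspline"` (default)** — coarse B-spline grid
  (16 mm control spacing) under **Mattes mutual information** (50 bins,
  seeded 10 % random sampling, L-BFGS-B). MI rather than MSD because a
  free-form deformation under MSD across contrast phases is degenerate:
  the optimizer collapses the enhanced blood pool to "explain" the
  +100 HU phase difference by warping. This is the path used by the ECV
  pipeline (cross-phase inputs).
* **Deformable, `method="demons"`** — dense multi-resolution
  fast-symmetric-forces demons displacement field. Faster and more
  accurate than the B-spline (mean residual < 0.5 mm against an applied
  2 mm smooth deformation), but it assumes intensity constancy and is
  only valid between same-phase volumes; cross-phase it fails even after
  histogram matching, because no monotone intensity map can reconcile a
  blood pool that enhances relative to the wall.

Resampling is cubic B-spline onto the fixed grid; out-of-field voxels
become NaN, a sentinel that propagates through `subtract` and is
excluded from every downstream mean — never silently filled with a
tissue value. Because cubic spline coefficients are global, a
NaN-bearing input is interpolated with sentinels neutralized and a
resampled validity mask re-flags any output voxel whose support touched
one.

## 4. LV model and readouts

Auto-contouring applies Otsu thresholding twice (body vs background,
then blood pool vs wall inside the body) with largest-component and
hole-filling morphology; it requires a contrast-bearing phase. Manual
per-slice polygon contours (JSON) are rasterized by voxel-centre-in-
polygon. The long axis is the cavity's principal SVD axis, oriented by
comparing end cross-sections (the apex is the narrow end).

Parcellation splits the base→apex axis: the most apical 10 % is the
excluded apex cap; the remainder divides into equal basal/mid/apical
thirds; basal and mid rings carry six 60° sectors from the reference
angle, the apical ring four 90° sectors offset by 45°. The blood-pool
ROI erodes the cavity by 3 mm (Euclidean distance transform) to avoid
partial-volume voxels. Normalized transmural depth is
`d_endo / (d_endo + d_epi)` from two distance transforms.

Enhancement classification thresholds the subtraction at the myocardial
mean + 3 SD, groups voxels into 26-connected 3-D lesions, drops lesions
below 0.1 mL, and calls a lesion ischemic when it touches the
endocardial quarter of the wall (depth < 0.25) — the computable
surrogate for a subendocardial/transmural pattern — marking all its
segments excluded; deeper lesions are nonischemic and kept.

## 5. Perfusion

Max-slope MBF: the tissue time–attenuation curve is smoothed with a
3-point moving average, differentiated with central differences, and the
maximum upslope divided by the arterial peak, ×6000 to yield
mL/100mL/min. The generator samples at dt = 0.5 s: with the mandated
smoothing and central differences, dt = 1 s incurs ~2.4 % discretization
bias (violating the 2 % noiseless recovery bound) while 0.5 s keeps it
~0.6 %. Segment MBF is normalized by the within-scan maximum and banded
(normalized > 0.75 → 0; (0.675, 0.75] → 1; (0.60, 0.675] → 2;
≤ 0.60 → 3, edges inclusive on the low side); the summed stress score
adds the 16 segment scores.

## 6. Morphometry

Agatston: per axial slice, 4-connected components of voxels ≥ 130 HU
with area ≥ 1 mm² contribute area × peak-density weight (130/200/300/400
HU → 1/2/3/4) × slice-thickness/3 mm. CAD-RADS bands the maximal
per-vessel stenosis with precedence: occlusion → 5; left main ≥ 50 % or
three vessels ≥ 70 % → 4B; any ≥ 70 % → 4A; ≥ 50 → 3; ≥ 25 → 2; ≥ 1 → 1;
obstructive = category ≥ 3. Chambers: biplane area–length left atrial
volume `8/(3π)·A1·A2/L`, modified Simpson LV volume, LV mass at
1.05 g/mL, Du Bois BSA for indexing. Effective dose = DLP × k with the
chest k-factor 0.014 mSv/(mGy·cm).

## 7. Statistics

Continuous variables route on Shapiro–Wilk at α = 0.05: normal →
mean ± SD and pooled t-test; otherwise median (IQR) and Mann–Whitney U.
2×2 tables use Pearson chi-square without continuity correction unless
an expected cell is < 5, then Fisher's exact (the chi-square route gives p = 0.29 for a
16/20-vs-13/20 table, matching common statistical-package defaults).
Correlation
is Pearson when both variables pass Shapiro–Wilk, else Spearman.

Propensity matching fits a logistic model (constant covariates dropped;
perfect separation raises), then greedily 1:1-matches treated subjects
in descending score order on the logit with an absolute caliper, without
replacement, seeded tie-breaking. Reproducibility: Bland–Altman bias ±
1.96 SD limits, within-subject CV `SD(diff)/√2 / grand mean`, and
ICC(2,1) (two-way random, absolute agreement, single measures).

Sample size solves the smallest per-group n by integer search over the
*exact* noncentral-t power function; at the design point delta = SD,
power 0.80, α 0.05 this gives 17/group where the normal approximation
understates it as 16.

## 8. Limitations

* The phantom is a geometric shell: no papillary muscles, trabeculae,
  coronary anatomy, breathing artifacts, or beam-hardening; real
  misalignment is not a global sinusoid.
* Contrast kinetics are reduced to a single equilibrium snapshot (ECV)
  and a noiseless gamma-variate input (perfusion); no recirculation or
  extraction-fraction effects.
* Auto-contouring assumes an enhanced blood pool and a single connected
  cavity; it is not a general cardiac segmenter.
* The demons deformable path requires same-phase inputs; cross-phase
  deformable accuracy is bounded by the MI B-spline stage (segment-mean
  ECV error ≈ 0.01, not voxelwise accuracy).
* Sector labels near boundaries depend on voxel size (≈ 2 % volume
  asymmetry at 1 mm); fine grids reduce this as expected.
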