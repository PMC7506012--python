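"""Seeded synthetic data with known ground truth.

Four generators emulate the inputs of the comprehensive cardiac-CT
analysis, each a pure function of its parameters and seed:

* :func:`generate_paired_ct` — paired pre-contrast/delayed-phase volumes
  of a half-ellipsoid LV shell whose per-segment attenuation change is
  the exact inversion of the ECV equation,
  ``dHU_myo = ECV * dHU_blood / (1 - Hct)``, optionally warped by a
  rigid + smooth misalignment and corrupted with Gaussian HU noise;
* :func:`generate_perfusion_series` — a gamma-variate arterial input and
  16 tissue time–attenuation curves whose maximum upslope encodes the
  requested myocardial blood flow;
* :func:`generate_calcium_volume` — an unenhanced volume carrying
  calcified plaques of requested area and peak HU on 3-mm slices;
* :func:`generate_cohort` — a two-group subject table (hemodialysis vs
  control) drawn at configurable means/SDs/prevalences with a requested
  within-group ECV–LAVI correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .core import CTVolume
from .errors import ValidationError
from .lvmodel import LVGeometry, parcellate_aha16, wall_depth

__all__ = [
    "Misalignment", "Lesion", "Plaque", "PhantomSpec", "PhantomTruth",
    "GroupParams", "CohortParams", "HD_GROUP", "CONTROL_GROUP",
    "generate_paired_ct", "generate_perfusion_series",
    "generate_calcium_volume", "generate_cohort",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Misalignment:
    """Physical motion of the delayed phase relative to the pre phase."""

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation_amplitude_mm: float = 0.0    # smooth sinusoidal field, <= 3 mm
    deformation_period_mm: float = 64.0

    @property
    def any(self) -> bool:
        return (any(abs(v) > 0 for v in self.translation_mm)
                or any(abs(v) > 0 for v in self.rotation_deg)
                or self.deformation_amplitude_mm > 0)


@dataclass(frozen=True)
class Lesion:
    """Delayed-enhancing lesion painted into one AHA segment.

    ``depth_min``/``depth_max`` bound the normalized transmural depth
    (0 = endocardium); a subendocardial lesion has depth_min 0, a
    midwall lesion a strictly positive depth_min.
    """

    segment: int                 # AHA label 1..16
    depth_max: float             # transmural extent fraction
    delta_hu: float              # HU boost on the delayed phase
    depth_min: float = 0.0


@dataclass(frozen=True)
class Plaque:
    center_mm: tuple[float, float, float]
    area_mm2: float
    peak_hu: float


# default per-segment truth: mild base-to-apex gradient around a normal ECV
_DEFAULT_ECV = tuple(np.round(np.linspace(0.22, 0.32, 16), 4))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and corruption parameters of the LV phantom."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)   # mm
    lv_center: tuple[float, float, float] = (48.0, 48.0, 66.0)  # base-plane centre, mm
    endo_radius: float = 16.0        # short-axis cavity radius, mm
    epi_radius: float = 26.0         # short-axis epicardial radius, mm
    long_axis_extent: float = 52.0   # base plane to apex tip, mm
    hu_blood_pre: float = 40.0
    hu_myo_pre: float = 40.0
    background_hu: float = -100.0
    delta_hu_blood: float = 100.0    # blood-pool enhancement pre -> delayed
    hematocrit: float = 0.40
    true_ecv: tuple[float, ...] = _DEFAULT_ECV
    noise_sd: float = 10.0           # i.i.d. Gaussian HU noise
    # smooth intra-tissue attenuation texture, identical in both phases
    # (cancels in an aligned subtraction); gives the deformable registrar
    # the structure real myocardium has, without which the tangential
    # component of a deformation is unidentifiable
    texture_sd_hu: float = 15.0
    texture_corr_mm: float = 4.0
    misalignment: Misalignment = field(default_factory=Misalignment)
    lesions: tuple[Lesion, ...] = ()
    ref_angle: float = 0.0           # radians; anchors AHA sector 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hematocrit < 1):
            raise ValidationError(f"hematocrit must be in (0,1), got {self.hematocrit}")
        if len(self.true_ecv) != 16:
            raise ValidationError("true_ecv must have 16 entries")
        if not all(0 < e < 1 for e in self.true_ecv):
            raise ValidationError("true_ecv values must be in (0,1)")
        if self.endo_radius >= self.epi_radius:
            raise ValidationError("zero- or negative-thickness wall "
                                  "(endo_radius >= epi_radius)")
        if self.long_axis_extent <= self.epi_radius - self.endo_radius:
            raise ValidationError("long axis too short for the wall thickness")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        c = np.asarray(self.lv_center)
        if (c[0] - self.epi_radius < 0 or c[0] + self.epi_radius > extent[0]
                or c[1] - self.epi_radius < 0 or c[1] + self.epi_radius > extent[1]
                or c[2] - self.long_axis_extent < 0 or c[2] > extent[2]):
            raise ValidationError("LV geometry does not fit the grid")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth carried alongside generated data for recovery tests."""

    spec: PhantomSpec | None = None
    geometry: LVGeometry | None = None
    true_ecv: np.ndarray | None = None          # (16,)
    delta_hu_myo: np.ndarray | None = None      # (16,) implied segment dHU
    lesion_masks: list[np.ndarray] = field(default_factory=list)
    resample_transform: object | None = None    # sitk.Transform applied to delayed
    rigid_params: dict | None = None            # physical motion parameters
    true_mbf: np.ndarray | None = None          # (16,) mL/100mL/min
    plaques: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# paired CT
# ---------------------------------------------------------------------------

def _rasterize_lv(spec: PhantomSpec) -> LVGeometry:
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x = sx * np.arange(nx)[:, None, None]
    y = sy * np.arange(ny)[None, :, None]
    z = sz * np.arange(nz)[None, None, :]
    cx, cy, cz = spec.lv_center
    wall = spec.epi_radius - spec.endo_radius
    c_epi = spec.long_axis_extent
    c_endo = spec.long_axis_extent - wall
    below_base = z <= cz
    epi = ((((x - cx) ** 2 + (y - cy) ** 2) / spec.epi_radius ** 2
            + (z - cz) ** 2 / c_epi ** 2) <= 1.0) & below_base
    endo = ((((x - cx) ** 2 + (y - cy) ** 2) / spec.endo_radius ** 2
             + (z - cz) ** 2 / c_endo ** 2) < 1.0) & below_base
    geom = LVGeometry(
        endo_mask=endo, epi_mask=epi, spacing=spec.spacing, origin=(0.0, 0.0, 0.0),
        base_pt=np.array([cx, cy, cz]), apex_pt=np.array([cx, cy, cz - c_epi]),
        ref_angle=spec.ref_angle,
    )
    return parcellate_aha16(geom)


def _misalignment_transform(spec: PhantomSpec) -> tuple[sitk.Transform, dict]:
    """Resampling transform encoding the physical motion of ``spec``.

    Built so that a registration of the warped delayed volume onto the
    pre volume recovers the physical parameters directly: the rigid part
    of the returned transform is the *inverse* of the physical motion.
    """
    mis = spec.misalignment
    cx, cy, cz = spec.lv_center
    center = (cx, cy, cz - spec.long_axis_extent / 2.0)

    phys = sitk.Euler3DTransform()
    phys.SetCenter(center)
    phys.SetRotation(*np.deg2rad(mis.rotation_deg))
    phys.SetTranslation(mis.translation_mm)
    rigid_resample = phys.GetInverse()

    params = {
        "translation_mm": tuple(mis.translation_mm),
        "rotation_deg": tuple(mis.rotation_deg),
        "center_mm": center,
        "deformation_amplitude_mm": mis.deformation_amplitude_mm,
        "deformation_period_mm": mis.deformation_period_mm,
    }
    if mis.deformation_amplitude_mm <= 0:
        return rigid_resample, params

    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    x = sx * np.arange(nx)[:, None, None]
    y = sy * np.arange(ny)[None, :, None]
    z = sz * np.arange(nz)[None, None, :]
    a = mis.deformation_amplitude_mm
    w = 2 * np.pi / mis.deformation_period_mm
    shape = spec.grid_shape
    dx = np.broadcast_to(a * np.sin(w * z), shape)
    dy = np.broadcast_to(a * np.sin(w * x + 1.0), shape)
    dz = np.broadcast_to(a * np.sin(w * y + 2.0), shape)
    field_arr = np.stack([dx, dy, dz], axis=-1)  # (nx, ny, nz, 3)
    field_img = sitk.GetImageFromArray(
        np.ascontiguousarray(field_arr.transpose(2, 1, 0, 3)), isVector=True)
    field_img.SetSpacing(spec.spacing)
    field_img = sitk.Cast(field_img, sitk.sitkVectorFloat64)
    deform = sitk.DisplacementFieldTransform(field_img)

    # composite applies the last-added transform first:
    # comp(p) = rigid_resample(deform(p))
    comp = sitk.CompositeTransform(3)
    comp.AddTransform(rigid_resample)
    comp.AddTransform(deform)
    return comp, params


def generate_paired_ct(spec: PhantomSpec) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """Paired pre-contrast and delayed-phase volumes with ground truth.

    The delayed phase equals the pre phase with the blood pool raised by
    ``delta_hu_blood`` and each AHA segment raised by the attenuation
    change implied by its true ECV, then warped by the requested
    misalignment and corrupted with independent Gaussian noise.
    """
    geom = _rasterize_lv(spec)
    labels = geom.labels
    cavity, myo = geom.endo_mask, geom.myo_mask

    pre = np.full(spec.grid_shape, spec.background_hu, float)
    pre[geom.epi_mask] = spec.hu_myo_pre
    pre[cavity] = spec.hu_blood_pre

    true_ecv = np.asarray(spec.true_ecv, float)
    dhu_myo = true_ecv * spec.delta_hu_blood / (1.0 - spec.hematocrit)
    ecv_map = np.zeros(spec.grid_shape)
    for seg in range(1, 17):
        ecv_map[labels == seg] = true_ecv[seg - 1]
    cap = myo & (labels == 0)
    ecv_map[cap] = true_ecv[12:].mean()      # apex cap follows the apical mean

    if spec.texture_sd_hu > 0:
        tex_rng = np.random.default_rng([spec.seed, 7])
        sig = [spec.texture_corr_mm / s for s in spec.spacing]
        tex = ndimage.gaussian_filter(tex_rng.standard_normal(spec.grid_shape), sig)
        tex *= spec.texture_sd_hu / tex.std()
        pre[geom.epi_mask] += tex[geom.epi_mask]

    delayed = pre.copy()
    delayed[cavity] += spec.delta_hu_blood
    delayed[myo] += ecv_map[myo] * spec.delta_hu_blood / (1.0 - spec.hematocrit)

    lesion_masks: list[np.ndarray] = []
    if spec.lesions:
        depth = wall_depth(geom)
        for les in spec.lesions:
            if not 1 <= les.segment <= 16:
                raise ValidationError(f"lesion segment {les.segment} out of range")
            m = ((labels == les.segment)
                 & (depth >= les.depth_min) & (depth <= les.depth_max))
            delayed[m] += les.delta_hu
            lesion_masks.append(m)

    transform = None
    rigid_params = None
    if spec.misalignment.any:
        transform, rigid_params = _misalignment_transform(spec)
        img = sitk.GetImageFromArray(np.ascontiguousarray(delayed.T))
        img.SetSpacing(spec.spacing)
        warped = sitk.Resample(img, img, transform, sitk.sitkLinear,
                               spec.background_hu, sitk.sitkFloat64)
        delayed = sitk.GetArrayFromImage(warped).T

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        delayed = delayed + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    truth = PhantomTruth(
        spec=spec, geometry=geom, true_ecv=true_ecv, delta_hu_myo=dhu_myo,
        lesion_masks=lesion_masks, resample_transform=transform,
        rigid_params=rigid_params,
    )
    meta = {"phase": "pre", "seed": spec.seed}
    pre_vol = CTVolume(pre, spec.spacing, meta=meta)
    del_vol = CTVolume(delayed, spec.spacing, meta={**meta, "phase": "delayed"})
    return pre_vol, del_vol, truth


# ---------------------------------------------------------------------------
# perfusion
# ---------------------------------------------------------------------------

def generate_perfusion_series(
    spec: PhantomSpec,
    true_mbf: np.ndarray,
    dt: float = 0.5,
    duration: float = 40.0,
    arterial_peak: float = 200.0,
    noise_sd: float = 0.0,
    t0: float = 4.0,
    time_to_peak: float = 8.0,
    gamma_alpha: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, PhantomTruth]:
    """Arterial input and 16 tissue time–attenuation curves.

    The arterial curve is a gamma variate peaking at ``arterial_peak``
    HU; tissue curve k is the running integral of the arterial curve
    scaled so its maximum upslope equals
    ``true_mbf[k] / 100 / 60 * arterial_peak`` HU/s, the maximum-slope
    encoding of myocardial blood flow in mL/100mL/min.

    Returns ``(t, arterial, tissue, truth)`` with ``tissue`` of shape
    (16, n_samples).
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    true_mbf = np.asarray(true_mbf, float)
    if true_mbf.shape != (16,):
        raise ValidationError("true_mbf must have 16 entries")
    if (true_mbf <= 0).any():
        raise ValidationError("true_mbf must be positive")

    t = np.arange(0.0, duration + dt / 2, dt)
    tau = np.clip(t - t0, 0.0, None) / time_to_peak
    arterial = arterial_peak * tau ** gamma_alpha * np.exp(gamma_alpha * (1.0 - tau))

    base = cumulative_trapezoid(arterial, t, initial=0.0)  # HU*s
    # d/dt tissue_k = mbf_k/6000 * A(t); maximum = mbf_k/6000 * arterial_peak
    tissue = (true_mbf[:, None] / 6000.0) * base[None, :]

    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        arterial = arterial + rng.normal(0.0, noise_sd, arterial.shape)
        tissue = tissue + rng.normal(0.0, noise_sd, tissue.shape)

    truth = PhantomTruth(spec=spec, true_mbf=true_mbf)
    return t, arterial, tissue, truth


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def generate_calcium_volume(
    spec: PhantomSpec,
    plaques: list[Plaque],
    grid_shape: tuple[int, int, int] = (64, 64, 8),
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0),
    background_mean: float = 20.0,
    background_sd: float = 12.0,
) -> tuple[CTVolume, PhantomTruth]:
    """Unenhanced volume with calcified plaques on 3-mm axial slices.

    Each plaque is painted as the ``round(area / pixel_area)`` in-plane
    pixels nearest its centre on its slice, all at the requested peak
    HU.  The background stays safely below the 130 HU calcium threshold.
    Overlapping plaques raise a warning; the truth then records the
    merged lesion (connected components of the final plaque mask).
    """
    for p in plaques:
        if p.peak_hu < 130:
            raise ValidationError(
                f"plaque peak {p.peak_hu} HU below the 130 HU scoring threshold")
        if p.area_mm2 <= 0:
            raise ValidationError("plaque area must be positive")

    rng = np.random.default_rng(spec.seed)
    data = rng.normal(background_mean, background_sd, grid_shape)
    data = np.clip(data, None, 115.0)        # background strictly below 130 HU
    sx, sy, sz = spacing
    pix_area = sx * sy

    plaque_mask = np.zeros(grid_shape, bool)
    for p in plaques:
        k = int(round(p.center_mm[2] / sz))
        if not 0 <= k < grid_shape[2]:
            raise ValidationError("plaque slice outside the grid")
        n_pix = max(1, int(round(p.area_mm2 / pix_area)))
        ii, jj = np.mgrid[0:grid_shape[0], 0:grid_shape[1]]
        d2 = (ii * sx - p.center_mm[0]) ** 2 + (jj * sy - p.center_mm[1]) ** 2
        order = np.argsort(d2.ravel())[:n_pix]
        sel = np.zeros(grid_shape[:2], bool)
        sel.ravel()[order] = True
        if (plaque_mask[:, :, k] & sel).any():
            warnings.warn("overlapping plaques merged into one lesion",
                          stacklevel=2)
        plaque_mask[:, :, k] |= sel
        data[:, :, k][sel] = np.maximum(data[:, :, k][sel], p.peak_hu)

    lesions = []
    for k in range(grid_shape[2]):
        lab, n = ndimage.label(plaque_mask[:, :, k],
                               structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for i in range(1, n + 1):
            m = lab == i
            lesions.append({
                "slice": k,
                "area_mm2": float(m.sum() * pix_area),
                "peak_hu": float(data[:, :, k][m].max()),
            })

    vol = CTVolume(data, spacing, meta={"seed": spec.seed})
    return vol, PhantomTruth(spec=spec, plaques=lesions)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Means/SDs and prevalences of one study arm."""

    ecv_mean: float
    ecv_sd: float
    hct_mean: float
    hct_sd: float
    lavi_mean: float
    lavi_sd: float
    lvmi_mean: float
    lvmi_sd: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    prev_male: float
    prev_hypertension: float
    prev_diabetes: float
    prev_dyslipidemia: float
    prev_smoking: float
    prev_prior_pci: float
    prev_prior_mi: float


# reference two-group study conditions: hemodialysis arm vs propensity-matched
# controls (ECV %, hematocrit %, LAVI mL/m2, LVMI g/m2, age y, BMI kg/m2)
HD_GROUP = GroupParams(
    ecv_mean=33.8, ecv_sd=4.7, hct_mean=33.4, hct_sd=5.0,
    lavi_mean=51.9, lavi_sd=22.4, lvmi_mean=90.9, lvmi_sd=28.9,
    age_mean=67.4, age_sd=9.6, bmi_mean=23.4, bmi_sd=3.8,
    prev_male=0.80, prev_hypertension=0.90, prev_diabetes=0.55,
    prev_dyslipidemia=0.45, prev_smoking=0.25, prev_prior_pci=0.30,
    prev_prior_mi=0.15,
)
CONTROL_GROUP = GroupParams(
    ecv_mean=26.6, ecv_sd=2.9, hct_mean=41.0, hct_sd=3.9,
    lavi_mean=30.2, lavi_sd=10.4, lvmi_mean=64.5, lvmi_sd=11.0,
    age_mean=66.3, age_sd=9.1, bmi_mean=23.7, bmi_sd=2.3,
    prev_male=0.85, prev_hypertension=0.80, prev_diabetes=0.50,
    prev_dyslipidemia=0.55, prev_smoking=0.25, prev_prior_pci=0.35,
    prev_prior_mi=0.20,
)


@dataclass(frozen=True)
class CohortParams:
    n_per_group: int = 20
    hd: GroupParams = HD_GROUP
    control: GroupParams = CONTROL_GROUP
    ecv_lavi_correlation: float = 0.54   # within-group Pearson rho
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be at least 2")
        if not abs(self.ecv_lavi_correlation) < 1:
            raise ValidationError("|correlation| must be < 1")
        for g in (self.hd, self.control):
            for name, val in vars(g).items():
                if name.startswith("prev_") and not 0 <= val <= 1:
                    raise ValidationError(f"{name} must be in [0,1]")
                if name.endswith("_sd") and val <= 0:
                    raise ValidationError(f"{name} must be > 0")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Two-group subject table with the requested statistical structure.

    Continuous variables are normal at the stated group means/SDs; ECV
    and LAVI are drawn jointly with the requested within-group Pearson
    correlation; binary covariates are Bernoulli at the stated
    prevalences.  One row per subject, ``group`` in {"HD", "control"}.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    rho = params.ecv_lavi_correlation
    for group, g in (("HD", params.hd), ("control", params.control)):
        n = params.n_per_group
        cov = np.array([[g.ecv_sd ** 2, rho * g.ecv_sd * g.lavi_sd],
                        [rho * g.ecv_sd * g.lavi_sd, g.lavi_sd ** 2]])
        ecv_lavi = rng.multivariate_normal([g.ecv_mean, g.lavi_mean], cov, size=n)
        df = pd.DataFrame({
            "group": group,
            "ecv_pct": ecv_lavi[:, 0],
            "lavi_ml_m2": ecv_lavi[:, 1],
            "hematocrit_pct": rng.normal(g.hct_mean, g.hct_sd, n),
            "lvmi_g_m2": rng.normal(g.lvmi_mean, g.lvmi_sd, n),
            "age": rng.normal(g.age_mean, g.age_sd, n),
            "bmi": rng.normal(g.bmi_mean, g.bmi_sd, n),
            "male": rng.random(n) < g.prev_male,
            "hypertension": rng.random(n) < g.prev_hypertension,
            "diabetes": rng.random(n) < g.prev_diabetes,
            "dyslipidemia": rng.random(n) < g.prev_dyslipidemia,
            "smoking": rng.random(n) < g.prev_smoking,
            "prior_pci": rng.random(n) < g.prev_prior_pci,
            "prior_mi": rng.random(n) < g.prev_prior_mi,
        })
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    bin_cols = ["male", "hypertension", "diabetes", "dyslipidemia",
                "smoking", "prior_pci", "prior_mi"]
    out[bin_cols] = out[bin_cols].astype(int)
    out.insert(0, "subject", np.arange(len(out)))
    return out
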