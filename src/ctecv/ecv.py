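"""Per-segment and per-patient extracellular volume (ECV).

The attenuation change of each AHA segment (dHUm) and of a blood-pool
ROI (dHUb) is read off the subtraction volume and converted with

    ECV = (dHUm / dHUb) * (1 - Hct)

Segments showing an ischemic delayed-enhancement pattern (a lesion with
subendocardial contact) are excluded; the per-patient ECV is the
unweighted mean over the remaining segments.  A polar (bullseye) map
renders the 16 values as fractions, hatching excluded segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .align import SubtractionVolume, apply_transform, register, subtract
from .core import CTVolume
from .errors import ValidationError
from .lvmodel import LVGeometry, blood_pool_roi, segment_lv, wall_depth

__all__ = [
    "SegmentECVTable", "delta_hu_myocardium", "delta_hu_blood", "ecv",
    "classify_delayed_enhancement", "patient_ecv", "ecv_polar_map",
    "run_ecv_pipeline",
]

N_SEGMENTS = 16
ENDOCARDIAL_DEPTH_BAND = 0.25   # lesion contact below this depth -> ischemic
MIN_LESION_ML = 0.1             # ignore noise specks below this volume


@dataclass
class SegmentECVTable:
    """Per-segment dHUm/ECV/class/exclusion plus the patient-level values.

    ``segments`` is indexed 1..16 with columns ``delta_hu_m`` (HU),
    ``ecv`` (fraction; NaN where excluded), ``enhancement`` (none |
    ischemic | nonischemic) and ``excluded``.
    """

    segments: pd.DataFrame
    delta_hu_b: float
    hematocrit: float
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def patient_ecv(self) -> float:
        return patient_ecv(self)

    def to_dict(self) -> dict:
        return {
            "segments": self.segments.reset_index()
                            .rename(columns={"index": "segment"})
                            .to_dict(orient="records"),
            "delta_hu_b": self.delta_hu_b,
            "hematocrit": self.hematocrit,
            "patient_ecv": self.patient_ecv,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# attenuation changes
# ---------------------------------------------------------------------------

def delta_hu_myocardium(sub: SubtractionVolume, geom: LVGeometry) -> np.ndarray:
    """Mean attenuation change of each AHA segment (16 values, HU).

    Sentinel (NaN) voxels are excluded from the mean; a segment with no
    usable voxels yields NaN rather than an error.
    """
    if geom.labels is None:
        raise ValidationError("geometry labels not filled; run parcellate_aha16")
    out = np.full(N_SEGMENTS, np.nan)
    for seg in range(1, N_SEGMENTS + 1):
        vals = sub.delta_hu[geom.labels == seg]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[seg - 1] = vals.mean()
    return out


def delta_hu_blood(sub: SubtractionVolume, roi: np.ndarray) -> float:
    """Mean attenuation change over the blood-pool ROI (HU)."""
    vals = sub.delta_hu[np.asarray(roi, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("empty blood-pool ROI")
    return float(vals.mean())


def ecv(delta_hu_m, delta_hu_b: float, hct: float):
    """ECV fraction from the attenuation-change ratio and hematocrit."""
    if not 0 < hct < 1:
        raise ValidationError(f"hematocrit must be in (0,1), got {hct}")
    if delta_hu_b == 0:
        raise ZeroDivisionError(
            "blood-pool attenuation change is zero; was contrast given and "
            "the ROI placed in the cavity?")
    return (np.asarray(delta_hu_m, float) / delta_hu_b) * (1.0 - hct)


# ---------------------------------------------------------------------------
# delayed-enhancement classification
# ---------------------------------------------------------------------------

def classify_delayed_enhancement(
    sub: SubtractionVolume,
    geom: LVGeometry,
    threshold: float | None = None,
) -> list[str]:
    """Per-segment enhancement class: none, ischemic or nonischemic.

    Voxels of the subtraction volume above ``threshold`` (default: mean
    myocardial dHU + 3 SD) are grouped into 3-D lesions; lesions smaller
    than ``MIN_LESION_ML`` are discarded.  A lesion reaching the
    endocardial band (normalized depth < 0.25) marks every segment it
    occupies as ischemic (the computable surrogate for a subendocardial
    or transmural pattern in a coronary distribution); a lesion confined
    to mid/epicardial depth marks its segments nonischemic.
    """
    if geom.labels is None:
        raise ValidationError("geometry labels not filled")
    myo = geom.myo_mask
    vals = sub.delta_hu[myo]
    vals = vals[np.isfinite(vals)]
    if threshold is None:
        threshold = float(vals.mean() + 3.0 * vals.std())

    hot = myo & (np.nan_to_num(sub.delta_hu, nan=-np.inf) > threshold)
    classes = ["none"] * N_SEGMENTS
    if not hot.any():
        return classes

    depth = wall_depth(geom)
    voxel_ml = float(np.prod(geom.spacing)) / 1000.0
    lab, n = ndimage.label(hot, structure=np.ones((3, 3, 3), int))
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() * voxel_ml < MIN_LESION_ML:
            continue
        subendo = np.nanmin(depth[m]) < ENDOCARDIAL_DEPTH_BAND
        cls = "ischemic" if subendo else "nonischemic"
        for seg in np.unique(geom.labels[m]):
            if seg < 1:
                continue
            prev = classes[seg - 1]
            if cls == "ischemic" or prev == "none":
                classes[seg - 1] = cls
    return classes


# ---------------------------------------------------------------------------
# patient-level
# ---------------------------------------------------------------------------

def patient_ecv(table: SegmentECVTable) -> float:
    """Unweighted mean ECV over non-excluded segments."""
    keep = table.segments.loc[~table.segments["excluded"], "ecv"]
    keep = keep[np.isfinite(keep)]
    if keep.empty:
        raise ValidationError("all 16 segments excluded; patient not evaluable")
    return float(keep.mean())


def build_segment_table(
    dhu_m: np.ndarray,
    dhu_b: float,
    hct: float,
    classes: list[str] | None = None,
    provenance: dict | None = None,
) -> SegmentECVTable:
    """Assemble the per-segment table, applying the ischemic-exclusion rule."""
    classes = classes or ["none"] * N_SEGMENTS
    excluded = np.array([c == "ischemic" for c in classes])
    ecv_vals = ecv(dhu_m, dhu_b, hct)
    warns: list[str] = []
    bad = np.isfinite(ecv_vals) & ((ecv_vals < 0) | (ecv_vals > 1))
    if bad.any():
        warns.append(
            f"ECV outside [0,1] in segments {list(np.flatnonzero(bad) + 1)}; "
            "values reported unclipped")
        warnings.warn(warns[-1], stacklevel=2)
    ecv_vals = np.where(excluded, np.nan, ecv_vals)   # ECV only where kept
    df = pd.DataFrame(
        {"delta_hu_m": dhu_m, "ecv": ecv_vals,
         "enhancement": classes, "excluded": excluded},
        index=pd.RangeIndex(1, N_SEGMENTS + 1, name="segment"),
    )
    return SegmentECVTable(df, float(dhu_b), float(hct), warns,
                           provenance or {})


# ---------------------------------------------------------------------------
# polar map
# ---------------------------------------------------------------------------

def ecv_polar_map(table: SegmentECVTable, ax=None, cmap: str = "viridis"):
    """AHA-16 bullseye of segment ECV values (rendered as fractions).

    Three rings (basal outer, mid, apical inner) with 6/6/4 sectors;
    excluded segments are hatched and carry no numeric annotation.
    Returns the matplotlib axes.
    """
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.patches import Wedge

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    vals = table.segments["ecv"].to_numpy()
    excluded = table.segments["excluded"].to_numpy()
    finite = vals[np.isfinite(vals)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    if vmax <= vmin:
        vmax = vmin + 1e-6
    norm = matplotlib.colors.Normalize(vmin, vmax)
    cm = matplotlib.colormaps[cmap]

    rings = [  # (r_inner, r_outer, n_sectors, first_label, angular offset deg)
        (2.0, 3.0, 6, 1, 0.0),
        (1.0, 2.0, 6, 7, 0.0),
        (0.0, 1.0, 4, 13, -45.0),
    ]
    for r_in, r_out, n_sec, first, offset in rings:
        width = 360.0 / n_sec
        for s in range(n_sec):
            seg = first + s
            v = vals[seg - 1]
            theta1 = s * width + offset
            kwargs = {}
            if excluded[seg - 1] or not np.isfinite(v):
                kwargs = {"facecolor": "lightgray", "hatch": "///"}
            else:
                kwargs = {"facecolor": cm(norm(v))}
            ax.add_patch(Wedge((0, 0), r_out, theta1, theta1 + width,
                               width=r_out - r_in, edgecolor="k", **kwargs))
            if not excluded[seg - 1] and np.isfinite(v):
                mid = np.deg2rad(theta1 + width / 2)
                r = (r_in + r_out) / 2
                ax.text(r * np.cos(mid), r * np.sin(mid), f"{v:.2f}",
                        ha="center", va="center", fontsize=8)
    ax.set_xlim(-3.2, 3.2)
    ax.set_ylim(-3.2, 3.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"ECV polar map (patient ECV {table.patient_ecv:.3f})")
    return ax


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_ecv_pipeline(
    pre: CTVolume,
    delayed: CTVolume,
    hct: float,
    geometry: LVGeometry | None = None,
    registration: str | None = "deformable",
    blood_margin_mm: float = 3.0,
    enhancement_threshold: float | None = None,
) -> SegmentECVTable:
    """Pre + delayed volumes -> per-segment and patient ECV.

    Steps: (1) register the delayed phase onto the pre phase (skipped
    when ``registration`` is None) and subtract; (2) delineate/parcellate
    the LV (auto-contoured on the delayed phase unless ``geometry`` is
    given) and erode the cavity for the blood-pool ROI; (3) read dHUm
    and dHUb off the subtraction, classify enhancement, exclude ischemic
    segments and average.
    """
    prov: dict = {"registration": registration,
                  "blood_margin_mm": blood_margin_mm}
    if registration is not None:
        t = register(delayed, pre, mode=registration)
        delayed_reg = apply_transform(delayed, t, reference=pre)
        prov["transform"] = t.provenance
    else:
        delayed_reg = delayed
    sub = subtract(delayed_reg, pre, provenance=prov)

    if geometry is None:
        from .lvmodel import parcellate_aha16
        geometry = parcellate_aha16(segment_lv(delayed_reg if registration
                                               else delayed))
    dhu_m = delta_hu_myocardium(sub, geometry)
    roi = blood_pool_roi(geometry, blood_margin_mm)
    dhu_b = delta_hu_blood(sub, roi)
    classes = classify_delayed_enhancement(sub, geometry,
                                           threshold=enhancement_threshold)
    return build_segment_table(dhu_m, dhu_b, hct, classes, provenance=prov)
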