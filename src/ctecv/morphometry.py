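"""Calcium scoring, CAD-RADS banding, chamber volumetry and dose.

Agatston score: per axial slice, 4-connected components of voxels at or
above 130 HU with in-plane area >= 1 mm^2 are lesions; each contributes
area (mm^2) x a peak-density weight (130-199 -> 1, 200-299 -> 2,
300-399 -> 3, >= 400 -> 4) x slice thickness / 3 mm.

CAD-RADS bands maximal per-vessel stenosis: 0 none, 1 (1-24%),
2 (25-49%), 3 (50-69%), 4A (70-99% in 1-2 vessels), 4B (70-99% in 3
vessels or left main >= 50%), 5 (any occlusion).  Obstructive CAD is
category >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume
from .errors import ValidationError

__all__ = [
    "CalciumLesion", "VesselStenosis", "ChamberMeasures",
    "agatston", "cad_rads", "la_volume_biplane", "simpson_biplane_volume",
    "lv_mass", "bsa_dubois", "index_to_bsa", "effective_dose",
]

CALCIUM_HU_THRESHOLD = 130.0
MIN_LESION_AREA_MM2 = 1.0
REFERENCE_SLICE_MM = 3.0
MYOCARDIAL_DENSITY_G_PER_ML = 1.05
DEFAULT_CHEST_K = 0.014          # mSv per mGy*cm


@dataclass(frozen=True)
class CalciumLesion:
    slice_index: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float


@dataclass(frozen=True)
class VesselStenosis:
    """Maximal stenosis per major vessel (%), left main separately."""

    lad: float = 0.0
    lcx: float = 0.0
    rca: float = 0.0
    left_main: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lad", "lcx", "rca", "left_main"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} stenosis must be in [0,100], got {v}")

    @property
    def vessels(self) -> tuple[float, float, float]:
        return (self.lad, self.lcx, self.rca)


@dataclass(frozen=True)
class ChamberMeasures:
    lvedv_ml: float
    lvesv_ml: float
    lv_mass_g: float
    la_volume_ml: float
    bsa_m2: float

    def __post_init__(self) -> None:
        if not 0 <= self.lvesv_ml <= self.lvedv_ml:
            raise ValidationError("need 0 <= LVESV <= LVEDV")

    @property
    def lvef(self) -> float:
        return (self.lvedv_ml - self.lvesv_ml) / self.lvedv_ml

    def indexed(self) -> dict:
        return {
            "lvedvi_ml_m2": index_to_bsa(self.lvedv_ml, self.bsa_m2),
            "lvesvi_ml_m2": index_to_bsa(self.lvesv_ml, self.bsa_m2),
            "lvmi_g_m2": index_to_bsa(self.lv_mass_g, self.bsa_m2),
            "lavi_ml_m2": index_to_bsa(self.la_volume_ml, self.bsa_m2),
        }


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def _density_weight(peak_hu: float) -> int:
    if peak_hu >= 400:
        return 4
    if peak_hu >= 300:
        return 3
    if peak_hu >= 200:
        return 2
    return 1


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def agatston(volume: CTVolume) -> tuple[float, list[CalciumLesion]]:
    """Total Agatston score and the per-lesion breakdown."""
    if volume.spacing is None:
        raise ValidationError("voxel spacing required")
    sx, sy, sz = volume.spacing
    pix_area = sx * sy
    thickness_factor = sz / REFERENCE_SLICE_MM
    lesions: list[CalciumLesion] = []
    for k in range(volume.shape[2]):
        sl = volume.data[:, :, k]
        mask = sl >= CALCIUM_HU_THRESHOLD
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=_FOUR_CONN)
        for i in range(1, n + 1):
            m = lab == i
            area = m.sum() * pix_area
            if area < MIN_LESION_AREA_MM2:
                continue
            peak = float(sl[m].max())
            w = _density_weight(peak)
            lesions.append(CalciumLesion(k, float(area), peak, w,
                                         float(area * w * thickness_factor)))
    return float(sum(l.score for l in lesions)), lesions


# ---------------------------------------------------------------------------
# CAD-RADS
# ---------------------------------------------------------------------------

def cad_rads(s: VesselStenosis) -> tuple[str, bool]:
    """Maximum-severity CAD-RADS category and the obstructive-CAD flag.

    Category 5 (any total occlusion) takes precedence over 4B; the
    left-main >= 50% rule is checked before the vessel-count rules.
    Obstructive CAD = category 3 or higher.
    """
    vessels = s.vessels
    all_stenoses = vessels + (s.left_main,)
    if any(v >= 100 for v in all_stenoses):
        cat = "5"
    elif s.left_main >= 50 or sum(v >= 70 for v in vessels) >= 3:
        cat = "4B"
    elif any(v >= 70 for v in all_stenoses):
        cat = "4A"
    elif any(v >= 50 for v in all_stenoses):
        cat = "3"
    elif any(v >= 25 for v in all_stenoses):
        cat = "2"
    elif any(v >= 1 for v in all_stenoses):
        cat = "1"
    else:
        cat = "0"
    obstructive = cat in ("3", "4A", "4B", "5")
    return cat, obstructive


# ---------------------------------------------------------------------------
# chamber volumetry
# ---------------------------------------------------------------------------

def la_volume_biplane(a1_cm2: float, a2_cm2: float, l_cm: float) -> float:
    """Biplane area-length volume V = (8 / 3*pi) * A1 * A2 / L, in mL."""
    if l_cm <= 0:
        raise ZeroDivisionError("long-axis length must be positive")
    if a1_cm2 < 0 or a2_cm2 < 0:
        raise ValidationError("areas must be non-negative")
    return (8.0 / (3.0 * np.pi)) * a1_cm2 * a2_cm2 / l_cm


def simpson_biplane_volume(diameters_4ch, diameters_2ch, length_cm: float) -> float:
    """Modified Simpson (method of discs) biplane volume in mL.

    V = (pi/4) * sum_i a_i * b_i * (L / n) with orthogonal disc
    diameters a_i, b_i (cm) from the 4- and 2-chamber views.
    """
    a = np.asarray(diameters_4ch, float)
    b = np.asarray(diameters_2ch, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("disc counts must match between views")
    if length_cm <= 0:
        raise ValidationError("length must be positive")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("diameters must be non-negative")
    return float(np.pi / 4.0 * np.sum(a * b) * (length_cm / a.size))


def lv_mass(myocardial_volume_ml: float) -> float:
    """LV mass (g) from myocardial volume at 1.05 g/mL."""
    if myocardial_volume_ml < 0:
        raise ValidationError("volume must be non-negative")
    return myocardial_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area: 0.007184 * H^0.725 * W^0.425 (m^2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height and weight must be positive")
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


def index_to_bsa(value: float, bsa_m2: float) -> float:
    """BSA-indexed value (per m^2)."""
    if bsa_m2 <= 0:
        raise ValidationError("BSA must be positive")
    return value / bsa_m2


def effective_dose(dlp_mgy_cm: float, k_msv_per_mgy_cm: float = DEFAULT_CHEST_K) -> float:
    """Effective dose (mSv) = DLP (mGy*cm) x body-region k-factor."""
    if dlp_mgy_cm < 0:
        raise ValidationError("DLP must be non-negative")
    return dlp_mgy_cm * k_msv_per_mgy_cm
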