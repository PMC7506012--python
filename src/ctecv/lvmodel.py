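"""Left-ventricular delineation and AHA 16-segment parcellation.

The myocardium is described by an endocardial (cavity) mask and an
epicardial (cavity + wall) mask on the CT grid, together with the long
axis (base centre -> apex) and a circumferential reference angle that
anchors sector 1 (the anterior RV-insertion surrogate).  Labels follow
the standard AHA numbering: basal 1-6 and mid-cavity 7-12 in 60-degree
sectors, apical 13-16 in 90-degree sectors offset by 45 degrees, apex
cap excluded (16-segment model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import CTVolume
from .errors import SegmentationError, ValidationError

__all__ = [
    "LVGeometry",
    "segment_lv",
    "parcellate_aha16",
    "blood_pool_roi",
    "wall_depth",
    "rasterize_contours",
    "load_contours",
]

BASAL_MID_BOUNDARY = 1.0 / 3.0
MID_APICAL_BOUNDARY = 2.0 / 3.0
APEX_CAP_FRACTION = 0.10  # most apical 10% of the axis is the excluded cap


@dataclass
class LVGeometry:
    """Masks, axes and AHA-16 label map for one left ventricle."""

    endo_mask: np.ndarray          # cavity (blood pool), bool
    epi_mask: np.ndarray           # cavity + wall, bool
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    base_pt: np.ndarray            # mm, centre of the mitral base plane
    apex_pt: np.ndarray            # mm, apex tip
    ref_angle: float = 0.0         # radians, anchors sector 1
    labels: np.ndarray | None = None   # int, 0 = background/apex cap

    def __post_init__(self) -> None:
        self.endo_mask = np.asarray(self.endo_mask, bool)
        self.epi_mask = np.asarray(self.epi_mask, bool)
        if self.endo_mask.shape != self.epi_mask.shape:
            raise ValidationError("endo and epi masks must share a grid")
        if (self.endo_mask & ~self.epi_mask).any():
            raise ValidationError("cavity must lie inside the epicardial mask")
        self.base_pt = np.asarray(self.base_pt, float)
        self.apex_pt = np.asarray(self.apex_pt, float)

    @property
    def myo_mask(self) -> np.ndarray:
        return self.epi_mask & ~self.endo_mask

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector from base centre to apex."""
        v = self.apex_pt - self.base_pt
        n = np.linalg.norm(v)
        if n == 0:
            raise ValidationError("degenerate long axis (apex == base)")
        return v / n

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = [
            self.origin[d] + self.spacing[d] * np.arange(self.endo_mask.shape[d])
            for d in range(3)
        ]
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def save_labels(self, nifti_path: str, legend_path: str | None = None) -> None:
        if self.labels is None:
            raise ValidationError("labels not filled; run parcellate_aha16 first")
        CTVolume(self.labels.astype(np.int16), self.spacing, self.origin).save(nifti_path)
        if legend_path:
            legend = {str(i): name for i, name in enumerate(AHA16_NAMES, start=1)}
            with open(legend_path, "w") as fh:
                json.dump(legend, fh, indent=1)


AHA16_NAMES = [
    "basal anterior", "basal anteroseptal", "basal inferoseptal",
    "basal inferior", "basal inferolateral", "basal anterolateral",
    "mid anterior", "mid anteroseptal", "mid inferoseptal",
    "mid inferior", "mid inferolateral", "mid anterolateral",
    "apical anterior", "apical septal", "apical inferior", "apical lateral",
]


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def segment_lv(
    volume: CTVolume,
    contours: dict | None = None,
    ref_angle: float = 0.0,
) -> LVGeometry:
    """Delineate LV cavity and wall.

    With ``contours`` (per-slice endo/epi polylines in voxel coordinates,
    see :func:`load_contours`), masks are rasterized from them.  Without,
    a threshold-and-morphology auto-contour is produced: Otsu separates
    the heart from the background, a second Otsu inside the heart
    separates the (contrast-bearing) blood pool from the wall.  The auto
    path is intended for contrast-enhanced phases where the cavity is
    brighter than the wall.
    """
    data = volume.data
    if contours is not None:
        endo = rasterize_contours(contours, "endo", data.shape)
        epi = rasterize_contours(contours, "epi", data.shape)
        epi |= endo
    else:
        finite = data[np.isfinite(data)]
        if finite.size == 0 or np.ptp(finite) < 50:
            raise SegmentationError("no tissue contrast in the volume (all air?)")
        body_thr = threshold_otsu(finite)
        body = np.nan_to_num(data, nan=-1000.0) > body_thr
        body = _largest_component(body)
        if not body.any():
            raise SegmentationError("no foreground object above threshold")
        body = ndimage.binary_fill_holes(body)
        inner = data[body]
        if np.ptp(inner) < 20:
            raise SegmentationError("cavity indistinguishable from wall "
                                    "(no contrast in the blood pool)")
        blood_thr = threshold_otsu(inner)
        endo = _largest_component(body & (np.nan_to_num(data, nan=-1000.0) > blood_thr))
        epi = body
        if not endo.any():
            raise SegmentationError("empty cavity after thresholding")

    if not endo.any():
        raise SegmentationError("empty cavity")
    base_pt, apex_pt = _axis_from_cavity(endo, volume.spacing, volume.origin)
    return LVGeometry(endo, epi, volume.spacing, volume.origin,
                      base_pt, apex_pt, ref_angle=ref_angle)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _axis_from_cavity(endo: np.ndarray, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    """Long axis from the cavity principal axis; apex = narrow end."""
    idx = np.argwhere(endo)
    pts = idx * np.asarray(spacing) + np.asarray(origin)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    lo, hi = proj.min(), proj.max()
    length = hi - lo
    # the apex end has the smaller cross-section
    span = 0.15 * length
    n_lo = int((proj < lo + span).sum())
    n_hi = int((proj > hi - span).sum())
    if n_lo < n_hi:           # low-projection end is narrower -> apex
        axis = -axis
        proj = -proj
        lo, hi = -hi, -lo
    base_pt = centroid + axis * lo
    apex_pt = centroid + axis * hi
    return base_pt, apex_pt


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def rasterize_contours(contours: dict, which: str, shape) -> np.ndarray:
    """Rasterize per-slice polygons: a voxel belongs to the mask when its
    centre lies inside the polygon of its slice.

    ``contours`` maps z-slice index -> {"endo": [[i, j], ...], "epi": ...}
    with vertices in voxel coordinates of the (x, y) plane.
    """
    mask = np.zeros(shape, bool)
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    centers = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    for k, polys in contours.items():
        poly = polys.get(which)
        if poly is None or len(poly) < 3:
            continue
        inside = MplPath(np.asarray(poly, float)).contains_points(centers)
        mask[:, :, int(k)] |= inside.reshape(shape[0], shape[1])
    return mask


def load_contours(path: str) -> dict:
    """Load JSON contours: {"<slice>": {"endo": [[i,j],...], "epi": [...]}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): v for k, v in raw.items()}


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def parcellate_aha16(geom: LVGeometry) -> LVGeometry:
    """Fill the AHA-16 label map in place (and return the geometry).

    The long axis from mitral base plane to the start of the apex cap is
    split into three equal thirds (basal/mid/apical); basal and mid rings
    carry 6 sectors of 60 degrees counted from the reference angle,
    the apical ring 4 sectors of 90 degrees offset by 45 degrees.  The
    most apical ``APEX_CAP_FRACTION`` of the axis (the cap) is excluded,
    i.e. labelled 0.
    """
    if geom.ref_angle is None or not np.isfinite(geom.ref_angle):
        raise ValidationError("reference angle undefined")
    axis = geom.long_axis
    length = float(np.linalg.norm(geom.apex_pt - geom.base_pt))
    e1, e2 = _inplane_basis(axis, geom.ref_angle)

    xg, yg, zg = geom.world_coords()
    px = xg - geom.base_pt[0]
    py = yg - geom.base_pt[1]
    pz = zg - geom.base_pt[2]
    t = (px * axis[0] + py * axis[1] + pz * axis[2]) / length
    theta = np.arctan2(
        px * e2[0] + py * e2[1] + pz * e2[2],
        px * e1[0] + py * e1[1] + pz * e1[2],
    ) % (2 * np.pi)

    labels = np.zeros(geom.endo_mask.shape, np.int16)
    myo = geom.myo_mask
    cap_start = 1.0 - APEX_CAP_FRACTION
    tn = t / cap_start                      # thirds of the non-cap axis
    deg = np.degrees(theta)

    basal = myo & (tn >= 0) & (tn < BASAL_MID_BOUNDARY)
    mid = myo & (tn >= BASAL_MID_BOUNDARY) & (tn < MID_APICAL_BOUNDARY)
    apical = myo & (tn >= MID_APICAL_BOUNDARY) & (tn < 1.0)

    labels[basal] = 1 + (deg[basal] // 60).astype(np.int16) % 6
    labels[mid] = 7 + (deg[mid] // 60).astype(np.int16) % 6
    labels[apical] = 13 + (((deg[apical] + 45) % 360) // 90).astype(np.int16) % 4
    geom.labels = labels
    return geom


def _inplane_basis(axis: np.ndarray, ref_angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the short-axis plane, rotated to ref_angle."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u0 = trial - np.dot(trial, axis) * axis
    u0 /= np.linalg.norm(u0)
    v0 = np.cross(axis, u0)
    e1 = np.cos(ref_angle) * u0 + np.sin(ref_angle) * v0
    e2 = np.cross(axis, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# blood pool and transmural depth
# ---------------------------------------------------------------------------

def blood_pool_roi(geom: LVGeometry, margin_mm: float) -> np.ndarray:
    """Cavity mask eroded by ``margin_mm`` to avoid partial-volume voxels."""
    if margin_mm < 0:
        raise ValidationError("margin must be non-negative")
    if not geom.endo_mask.any():
        raise ValidationError("empty cavity")
    dist = ndimage.distance_transform_edt(geom.endo_mask, sampling=geom.spacing)
    roi = dist > margin_mm
    if not roi.any():
        raise ValidationError(
            f"margin {margin_mm} mm empties the cavity; use a smaller margin")
    return roi


def wall_depth(geom: LVGeometry) -> np.ndarray:
    """Normalized transmural depth over the myocardium.

    0 at the endocardial surface, 1 at the epicardial surface, NaN
    outside the wall.  Computed from Euclidean distance transforms to
    the cavity and to the outside of the epicardial solid.
    """
    d_endo = ndimage.distance_transform_edt(~geom.endo_mask, sampling=geom.spacing)
    d_epi = ndimage.distance_transform_edt(geom.epi_mask, sampling=geom.spacing)
    depth = np.full(geom.endo_mask.shape, np.nan)
    myo = geom.myo_mask
    total = d_endo[myo] + d_epi[myo]
    with np.errstate(invalid="ignore"):
        depth[myo] = np.where(total > 0, d_endo[myo] / total, 0.0)
    return depth
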