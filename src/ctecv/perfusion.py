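"""Myocardial blood flow from dynamic curves and the summed stress score.

Per-segment MBF is estimated with a maximum-slope method: the largest
upslope of the (lightly smoothed) tissue time–attenuation curve divided
by the arterial peak, converted to mL/100mL/min.  Segment values are
normalized by the cohort-free within-scan maximum and banded into a
severity score; the summed stress score (SSS) adds the 16 segment
scores:

    0  normal              normalized MBF >  0.75
    1  mildly abnormal     0.675 < normalized MBF <= 0.75
    2  moderately abnormal 0.60  < normalized MBF <= 0.675
    3  severely abnormal   normalized MBF <= 0.60
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["PerfusionResult", "mbf_max_slope", "normalized_mbf",
           "segment_score", "sss", "analyze_perfusion"]

SCORE_BANDS = (0.75, 0.675, 0.60)   # inclusive on the low side


@dataclass
class PerfusionResult:
    """Per-segment MBF / normalized MBF / score plus the global summaries."""

    segments: pd.DataFrame          # index 1..16: mbf, normalized, score
    global_mbf: float               # mean of the 16 segment MBFs
    sss: int

    def to_dict(self) -> dict:
        return {"segments": self.segments.reset_index().to_dict(orient="records"),
                "global_mbf": self.global_mbf, "sss": self.sss}


def mbf_max_slope(tissue_tac: np.ndarray, arterial_tac: np.ndarray,
                  dt: float) -> float:
    """MBF (mL/100mL/min) = max upslope of the tissue curve / arterial peak.

    The tissue curve is smoothed with a 3-point moving average and
    differentiated with central differences; the result is scaled by
    6000 (100 mL x 60 s).  A negative estimate is floored at 0 with a
    warning.
    """
    tissue = np.asarray(tissue_tac, float)
    arterial = np.asarray(arterial_tac, float)
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if tissue.size < 4 or arterial.size < 4:
        raise ValidationError("need at least 4 samples")
    peak = float(arterial.max())
    if peak <= 0 or np.ptp(arterial) == 0:
        raise ValidationError("flat or non-positive arterial curve")

    kernel = np.ones(3) / 3.0
    smooth = np.convolve(tissue, kernel, mode="valid")   # 3-pt moving average
    slope = float(np.max(np.gradient(smooth, dt)))
    mbf = slope / peak * 6000.0
    if mbf < 0:
        warnings.warn("negative MBF estimate floored at 0", stacklevel=2)
        return 0.0
    return mbf


def normalized_mbf(segment_mbf: np.ndarray) -> np.ndarray:
    """Each segment's MBF divided by the highest of the 16 segments."""
    v = np.asarray(segment_mbf, float)
    if v.shape != (16,):
        raise ValidationError("expected 16 segment MBF values")
    top = v.max()
    if top <= 0:
        raise ValidationError("all-zero MBF; cannot normalize")
    return v / top


def segment_score(normalized: float) -> int:
    """Severity score 0-3 from normalized MBF (band edges inclusive low)."""
    if not 0 < normalized <= 1:
        raise ValidationError(f"normalized MBF must be in (0,1], got {normalized}")
    if normalized > SCORE_BANDS[0]:
        return 0
    if normalized > SCORE_BANDS[1]:
        return 1
    if normalized > SCORE_BANDS[2]:
        return 2
    return 3


def sss(scores) -> int:
    """Summed stress score: the sum of the 16 segment scores."""
    scores = list(scores)
    if len(scores) != 16:
        raise ValidationError("expected 16 segment scores")
    if any(int(s) != s or not 0 <= s <= 3 for s in scores):
        raise ValidationError("scores must be integers in 0..3")
    return int(sum(scores))


def analyze_perfusion(tissue_tacs: np.ndarray, arterial_tac: np.ndarray,
                      dt: float) -> PerfusionResult:
    """16 tissue curves + arterial input -> MBF table, global MBF, SSS."""
    tacs = np.asarray(tissue_tacs, float)
    if tacs.shape[0] != 16:
        raise ValidationError("expected 16 tissue curves")
    mbf = np.array([mbf_max_slope(tacs[k], arterial_tac, dt) for k in range(16)])
    norm = normalized_mbf(mbf)
    scores = [segment_score(n) for n in norm]
    df = pd.DataFrame({"mbf": mbf, "normalized": norm, "score": scores},
                      index=pd.RangeIndex(1, 17, name="segment"))
    return PerfusionResult(df, float(mbf.mean()), sss(scores))
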