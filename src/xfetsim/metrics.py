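"""ROI statistics, CNR, Rose-criterion detectability and detection limits.

The contrast-to-noise ratio of a gold region is

    CNR = (C_Au - C_bkg) / sigma_bkg

with ROI means and the sample (n-1) standard deviation of the background.
A region is detectable when CNR >= 4 (Rose criterion; the boundary counts as
detectable).  Detection limits come from the CNR = 4 crossing of a linear
CNR-versus-concentration fit per depth; limits versus depth are summarized
by an exponential fit whose depth-zero intercept is the surface detection
limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import ROISpec

ROSE_THRESHOLD = 4.0


@dataclass
class CNRResult:
    """Per-ROI CNR with replicate spread."""

    label: str
    c_gold: float               # mean signal in the gold ROI
    c_bkg: float
    sigma_bkg: float
    cnr: float
    cnr_replicates: np.ndarray | None = None

    @property
    def cnr_mean(self) -> float:
        return float(np.mean(self.cnr_replicates)) \
            if self.cnr_replicates is not None else self.cnr

    @property
    def cnr_sd(self) -> float:
        return float(np.std(self.cnr_replicates, ddof=1)) \
            if self.cnr_replicates is not None and len(self.cnr_replicates) > 1 \
            else 0.0


@dataclass
class DetectionLimitFit:
    """Per-depth linear fits and the exponential depth extrapolation."""

    depths_mm: np.ndarray
    limits_wt_pct: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    surface_limit_wt_pct: float   # a in limit(z) = a * exp(b z)
    decay_per_mm: float           # b


def roi_stats(image_xy: np.ndarray, roi: ROISpec, pitch_mm: float,
              origin_xy) -> tuple[float, float, int]:
    """Mean, sample SD and voxel count over ROI-interior voxel centers."""
    mask = roi.mask(image_xy.shape, pitch_mm, origin_xy)
    vals = image_xy[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no voxels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def cnr(c_gold: float, c_bkg: float, sigma_bkg: float) -> float:
    if sigma_bkg <= 0:
        raise ZeroDivisionError("background SD must be positive for CNR")
    return (c_gold - c_bkg) / sigma_bkg


def rose_detectable(cnr_value: float) -> bool:
    """Detectable iff CNR >= 4 (boundary inclusive)."""
    return cnr_value >= ROSE_THRESHOLD


def measure_cnr(image_xy: np.ndarray, gold_roi: ROISpec, bkg_roi: ROISpec,
                pitch_mm: float, origin_xy) -> CNRResult:
    """CNR of one gold ROI against one background ROI on a 2D slice."""
    c_au, _, _ = roi_stats(image_xy, gold_roi, pitch_mm, origin_xy)
    c_bkg, s_bkg, _ = roi_stats(image_xy, bkg_roi, pitch_mm, origin_xy)
    return CNRResult(gold_roi.label, c_au, c_bkg, s_bkg,
                     cnr(c_au, c_bkg, s_bkg))


def detection_limit(concentrations_wt_pct, cnrs) -> tuple[float, float, float]:
    """Gold concentration at which the fitted CNR line crosses 4.

    Returns ``(limit_wt_pct, slope, intercept)``; requires at least two
    points and a positive fitted slope.
    """
    c = np.asarray(concentrations_wt_pct, dtype=float)
    y = np.asarray(cnrs, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two concentration points")
    fit = stats.linregress(c, y)
    if not fit.slope > 0:
        raise ValueError("non-positive CNR-vs-concentration slope; no limit")
    return (ROSE_THRESHOLD - fit.intercept) / fit.slope, fit.slope, fit.intercept


def extrapolate_surface_limit(depths_mm, limits_wt_pct) -> DetectionLimitFit:
    """Exponential fit limit(z) = a exp(b z) via least squares on ln(limit)."""
    z = np.asarray(depths_mm, dtype=float)
    lim = np.asarray(limits_wt_pct, dtype=float)
    if z.size < 3:
        raise ValueError("need at least three depth points")
    if np.any(lim <= 0):
        raise ValueError("detection limits must be positive")
    b, ln_a = np.polyfit(z, np.log(lim), 1)
    return DetectionLimitFit(z, lim, np.array([]), np.array([]),
                             float(np.exp(ln_a)), float(b))


def fit_cnr_vs_concentration(concentrations_wt_pct, cnrs):
    """Linear fit diagnostics: (slope, intercept, r_squared)."""
    fit = stats.linregress(np.asarray(concentrations_wt_pct, float),
                           np.asarray(cnrs, float))
    return fit.slope, fit.intercept, fit.rvalue ** 2


def comparison_report(cnr_by_modality: dict[str, list[CNRResult]]) -> pd.DataFrame:
    """Ranked CNR table with pairwise percent improvements.

    Percent improvement of modality A over B is the mean of per-ROI CNR
    ratios minus one, times 100 (mean-of-ratios convention).  All modalities
    must report the same ROI labels.
    """
    labels = [r.label for r in next(iter(cnr_by_modality.values()))]
    for mod, results in cnr_by_modality.items():
        if [r.label for r in results] != labels:
            raise ValueError(f"ROI set of {mod!r} does not match")
    rows = []
    for mod, results in cnr_by_modality.items():
        for r in results:
            rows.append({"modality": mod, "roi": r.label, "cnr": r.cnr_mean,
                         "cnr_sd": r.cnr_sd,
                         "rose_detectable": rose_detectable(r.cnr_mean)})
    table = pd.DataFrame(rows)
    means = {m: np.array([r.cnr_mean for r in res])
             for m, res in cnr_by_modality.items()}
    for a in means:
        for b in means:
            if a != b:
                ratio = float(np.mean(means[a] / means[b]))
                table.attrs[f"improvement_{a}_over_{b}_pct"] = 100 * (ratio - 1)
    return table.sort_values(["roi", "cnr"], ascending=[True, False]) \
        .reset_index(drop=True)
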