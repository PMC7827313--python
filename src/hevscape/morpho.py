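"""Per-vessel morphometry: lumen diameter, dilation class, endothelial
thickness, PNAd perimeter continuity.

The manual caliper protocol behind the dilation classes ("mean of three
measurements of the shortest cross-sectional diameter") is operationalized
as the inscribed-circle diameter: twice the Euclidean distance-transform
value on the lumen medial axis, averaged over up to the three largest
medial-axis local maxima. For a disc this is the diameter, for an elongated
lumen it is the shortest cross-section, and it is deterministic.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .config import AnalysisConfig
from .imgio import Calibration

__all__ = ["lumen_diameter_um", "classify_dilation", "ec_thickness_um",
           "pnad_coverage"]


def _medial_axis_edt(mask: np.ndarray):
    """Skeleton of a padded mask plus its Euclidean distance transform."""
    padded = np.pad(mask, 1)
    skel = skeletonize(padded)
    dist = ndimage.distance_transform_edt(padded)
    return skel, dist


def _skeleton_peak_values(mask: np.ndarray, n_peaks: int = 3) -> np.ndarray:
    """Values of the EDT at the largest local maxima on the medial axis.

    Adjacent peak pixels (plateaus) are clustered; each cluster contributes
    its maximum once. Returns up to ``n_peaks`` values, largest first; fewer
    if the medial axis is degenerate (e.g. a disc has a single peak).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.array([])
    skel, dist = _medial_axis_edt(mask)
    if not skel.any():
        return np.array([])
    dmax = ndimage.maximum_filter(np.where(skel, dist, 0.0), size=3)
    peaks = skel & (dist >= dmax - 1e-9)
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3)))
    if n == 0:
        return np.array([])
    vals = ndimage.maximum(dist, labels, index=np.arange(1, n + 1))
    vals = np.sort(np.atleast_1d(vals))[::-1]
    return vals[:n_peaks]


def lumen_diameter_um(lumen_mask: np.ndarray, calibration: Calibration) -> float:
    """Shortest-cross-section lumen diameter in µm; 0 for an empty mask."""
    mask = np.asarray(lumen_mask, bool)
    if not mask.any():
        return 0.0
    vals = _skeleton_peak_values(mask, n_peaks=3)
    if vals.size == 0:  # single-pixel degenerate lumen
        return float(2.0 * calibration.um_per_px)
    return float(2.0 * vals.mean() * calibration.um_per_px)


def classify_dilation(diameter_um: float, config: AnalysisConfig) -> str:
    """NON (closed), INT (< cutoff) or HIGH (>= cutoff, boundary upward)."""
    if diameter_um < 0:
        raise ValueError(f"diameter must be >= 0, got {diameter_um}")
    if diameter_um == 0:
        return "NON"
    if diameter_um < config.dilation_high_um:
        return "INT"
    return "HIGH"


def ec_thickness_um(wall_mask: np.ndarray, calibration: Calibration,
                    config: AnalysisConfig | None = None) -> Tuple[float, bool]:
    """Mean endothelial width along the wall medial axis, and the thin flag.

    The local wall width is twice the distance-transform value on the
    medial axis; the mean over the whole annulus gives one thickness per
    vessel. The thin flag compares it against ``config.thin_ec_um``
    (default 3 µm; the qualitative criterion "lack of cuboidal endothelium"
    has no printed numeric value, so the threshold is a config field).
    """
    mask = np.asarray(wall_mask, bool)
    if not mask.any():
        raise ValueError("ec_thickness_um: empty wall mask")
    skel, dist = _medial_axis_edt(mask)
    if not skel.any():
        thickness = float(2.0 * dist.max() * calibration.um_per_px)
    else:
        thickness = float(2.0 * dist[skel].mean() * calibration.um_per_px)
    cfg = config or AnalysisConfig()
    return thickness, thickness < cfg.thin_ec_um


def _wall_angular_profile(wall_mask: np.ndarray, positive: np.ndarray,
                          n_bins: int) -> Tuple[np.ndarray, np.ndarray, float]:
    """Per-angular-bin wall pixel counts and positive-pixel counts.

    Angles are measured around the wall's interior reference point: the
    lumen centroid when the wall encloses a lumen, else the wall centroid.
    Also returns the mean wall radius in pixels (for arc-length conversion).
    """
    ys, xs = np.nonzero(wall_mask)
    filled = ndimage.binary_fill_holes(wall_mask)
    lumen = filled & ~wall_mask
    if lumen.any():
        ly, lx = np.nonzero(lumen)
        cy, cx = float(ly.mean()), float(lx.mean())
    else:
        cy, cx = float(ys.mean()), float(xs.mean())
    ang = np.mod(np.arctan2(ys - cy, xs - cx), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    wall_counts = np.bincount(bins, minlength=n_bins)
    pos_counts = np.bincount(bins, weights=positive[ys, xs].astype(float),
                             minlength=n_bins)
    mid_radius_px = float(np.hypot(ys - cy, xs - cx).mean())
    return wall_counts, pos_counts, mid_radius_px


def _longest_negative_run(neg: np.ndarray) -> int:
    """Longest circular run of True values."""
    if neg.all():
        return int(neg.size)
    if not neg.any():
        return 0
    # rotate so the sequence starts on a False, then measure linear runs
    start = int(np.argmin(neg))
    rolled = np.roll(neg, -start)
    best = cur = 0
    for v in rolled:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return int(best)


def pnad_coverage(wall_mask: np.ndarray, pnad_plane: np.ndarray,
                  config: AnalysisConfig, calibration: Calibration,
                  pnad_positive: np.ndarray | None = None) -> Tuple[float, bool]:
    """PNAd coverage of the wall perimeter and the discontinuity flag.

    Coverage is the fraction of angular bins (default 72) around the lumen
    centroid whose wall pixels are majority-PNAd+. The wall is flagged
    discontinuous when coverage falls below ``pnad_discontinuous_max`` AND
    the longest contiguous negative arc is at least ``pnad_min_gap_um``
    long, measured at the wall mid-radius — a guard against calling
    pixel-level noise "discontinuous".
    """
    mask = np.asarray(wall_mask, bool)
    if not mask.any():
        raise ValueError("pnad_coverage: empty wall mask")
    if pnad_positive is None:
        from .imgio import to_8bit_scale
        plane = to_8bit_scale(pnad_plane)
        pnad_positive = plane >= config.positivity_threshold("PNAD", plane)
    wall_counts, pos_counts, mid_r_px = _wall_angular_profile(
        mask, pnad_positive, config.n_angular_bins)
    occupied = wall_counts > 0
    if not occupied.any():
        return 0.0, True
    pos_bin = occupied & (pos_counts > 0.5 * wall_counts)
    coverage = float(pos_bin.sum()) / float(occupied.sum())
    # gap length in arc µm at the wall mid-radius (only occupied bins count)
    neg = occupied & ~pos_bin
    # collapse to the occupied-bin circle so empty bins don't break runs
    neg_seq = neg[occupied]
    run = _longest_negative_run(neg_seq)
    gap_um = run / float(occupied.sum()) * 2 * np.pi * mid_r_px * calibration.um_per_px
    discontinuous = (coverage < config.pnad_discontinuous_max) and \
        (gap_um >= config.pnad_min_gap_um)
    return coverage, discontinuous
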