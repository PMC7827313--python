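"""Perivascular stroma scoring and CCL21+ lymphocyte analysis.

Markers (CCL21, aSMA, heparan sulfate) are scored on a ring just outside
the vessel wall: coverage is the fraction of angular bins containing
positive signal, mapped to CONTINUOUS / PARTIAL / NONE by two config
cutoffs. CCL21 staining morphology is classified per LN into reticular
(FRC network) versus immune-cell (compact CCL21-coated lymphocyte blobs)
by the fraction of CCL21+ area in blob-shaped components. CD3 co-positivity
of the blobs around highly dilated vessels is scored in the four ordinal
categories 100% / >50% / <50% / 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from . import _geom
from .config import AnalysisConfig
from .hevseg import VesselRecord
from .imgio import Calibration, MultiplexImage, to_8bit_scale

CATEGORY_NA = "NA"


@dataclass(frozen=True)
class CoverageScore:
    marker: str
    coverage: float
    category: str  # CONTINUOUS / PARTIAL / NONE / NA


@dataclass
class CellBlob:
    """A compact CCL21+ object with lymphocyte morphology."""

    centroid_um: Tuple[float, float]  # (x, y)
    area_um2: float
    circularity: float
    ccl21_pos: bool = True
    asma_pos: bool = False
    cd3_pos: bool = False


def categorize(coverage: float, config: AnalysisConfig) -> str:
    """Map a coverage fraction to CONTINUOUS / PARTIAL / NONE."""
    if coverage >= config.coverage_continuous_min:
        return "CONTINUOUS"
    if coverage <= config.coverage_none_max:
        return "NONE"
    return "PARTIAL"


def perivascular_ring(vessel: VesselRecord, config: AnalysisConfig,
                      calibration: Calibration,
                      occupied_labels: Optional[np.ndarray] = None
                      ) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Ring mask of pixels within ``ring_width_um`` outside the vessel wall.

    Other vessels' walls and lumens (given by ``occupied_labels``, a
    full-frame int array with vessel_id+1 painted over wall+lumen) are
    excluded. Returns the ring as a crop plus its (row0, col0) offset.
    """
    if not vessel.wall_mask.any():
        raise ValueError("perivascular_ring: empty wall mask")
    upp = calibration.um_per_px
    pad = int(np.ceil(config.ring_width_um / upp)) + 2
    r0, r1, c0, c1 = vessel.bbox
    if occupied_labels is not None:
        h, w = occupied_labels.shape
    else:
        h, w = r1 + pad, c1 + pad
    R0, R1 = max(0, r0 - pad), min(h, r1 + pad)
    C0, C1 = max(0, c0 - pad), min(w, c1 + pad)
    wall = np.zeros((R1 - R0, C1 - C0), bool)
    wall[r0 - R0:r1 - R0, c0 - C0:c1 - C0] = vessel.wall_mask
    lumen = np.zeros_like(wall)
    lumen[r0 - R0:r1 - R0, c0 - C0:c1 - C0] = vessel.lumen_mask
    if config.ring_width_um <= 0:
        return np.zeros_like(wall), (R0, C0)
    ring = _geom.dilate_um(wall, config.ring_width_um, upp) & ~wall & ~lumen
    if occupied_labels is not None:
        others = occupied_labels[R0:R1, C0:C1]
        ring &= ~((others > 0) & (others != vessel.vessel_id + 1))
    return ring, (R0, C0)


def score_marker(ring: np.ndarray, plane: np.ndarray, config: AnalysisConfig,
                 marker: str = "marker",
                 center_rc: Optional[Tuple[float, float]] = None,
                 positive: Optional[np.ndarray] = None) -> CoverageScore:
    """Angular coverage of positive signal in a perivascular ring.

    ``ring`` and ``plane`` are matching (cropped) arrays. Coverage is the
    fraction of angular bins around the ring centre whose ring pixels hold
    at least ``min_positive_px_per_bin`` positive pixels. An empty ring
    yields an NA score.
    """
    ring = np.asarray(ring, bool)
    if not ring.any():
        return CoverageScore(marker=marker, coverage=float("nan"),
                             category=CATEGORY_NA)
    if positive is None:
        arr = to_8bit_scale(plane)
        positive = arr >= config.positivity_threshold(marker, arr)
    ys, xs = np.nonzero(ring)
    if center_rc is None:
        cy, cx = float(ys.mean()), float(xs.mean())
    else:
        cy, cx = center_rc
    ang = np.mod(np.arctan2(ys - cy, xs - cx), 2 * np.pi)
    n_bins = config.n_angular_bins
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    ring_counts = np.bincount(bins, minlength=n_bins)
    pos_counts = np.bincount(bins, weights=positive[ys, xs].astype(float),
                             minlength=n_bins)
    occupied = ring_counts > 0
    pos_bin = occupied & (pos_counts >= config.min_positive_px_per_bin)
    coverage = float(pos_bin.sum()) / float(occupied.sum())
    return CoverageScore(marker=marker, coverage=coverage,
                         category=categorize(coverage, config))


def detect_blobs(ccl21_plane: np.ndarray, asma_plane: np.ndarray,
                 cd3_plane: Optional[np.ndarray], region_mask: np.ndarray,
                 config: AnalysisConfig, calibration: Calibration
                 ) -> Tuple[List[CellBlob], float, float]:
    """Decompose CCL21+ signal into lymphocyte-shaped blobs vs. remainder.

    Returns (blobs, blob_positive_area_um2, total_positive_area_um2). A blob
    is a connected CCL21+ component whose hole-filled outline has area within
    the configured bounds and circularity >= the configured minimum; its
    aSMA and CD3 flags come from the mean intensity inside the filled
    outline. aSMA+ blobs are kept in the list but flagged (they are excluded
    from immune-cell candidates downstream).
    """
    upp2 = calibration.um2_per_px2()
    ccl21 = to_8bit_scale(ccl21_plane)
    pos = (ccl21 >= config.positivity_threshold("CCL21", ccl21)) & region_mask
    total_area = float(pos.sum()) * upp2
    if total_area == 0:
        return [], 0.0, 0.0
    asma = to_8bit_scale(asma_plane)
    asma_thr = config.positivity_threshold("ASMA", asma)
    cd3 = to_8bit_scale(cd3_plane) if cd3_plane is not None else None
    cd3_thr = config.positivity_threshold("CD3", cd3) if cd3 is not None else None

    labels, n = ndimage.label(pos)
    blobs: List[CellBlob] = []
    blob_area_px = 0.0
    # cheap size prefilter: a blob's raw positive area cannot be smaller than
    # a third of the minimum filled area nor exceed the maximum filled area
    sizes = np.bincount(labels.ravel())
    lo = config.blob_min_area_um2 / upp2 / 3.0
    hi = config.blob_max_area_um2 / upp2
    keep = np.flatnonzero((sizes >= lo) & (sizes <= hi))
    keep = keep[keep > 0]
    if keep.size == 0:
        return [], 0.0, total_area
    cand = np.where(np.isin(labels, keep), labels, 0)
    for prop in regionprops(cand):
        filled_area_um2 = prop.area_filled * upp2
        if not (config.blob_min_area_um2 <= filled_area_um2 <= config.blob_max_area_um2):
            continue
        perim = prop.perimeter
        if perim <= 0:
            continue
        circ = min(4 * np.pi * prop.area_filled / perim ** 2, 1.0)
        if circ < config.blob_min_circularity:
            continue
        r0, c0, r1, c1 = prop.bbox
        interior = prop.image_filled
        sl = (slice(r0, r1), slice(c0, c1))
        asma_pos = float(asma[sl][interior].mean()) >= asma_thr
        cd3_pos = bool(cd3 is not None
                       and float(cd3[sl][interior].mean()) >= cd3_thr)
        cy, cx = prop.centroid
        blobs.append(CellBlob(
            centroid_um=(cx * calibration.um_per_px, cy * calibration.um_per_px),
            area_um2=filled_area_um2, circularity=float(circ),
            asma_pos=bool(asma_pos), cd3_pos=cd3_pos))
        if not asma_pos:
            blob_area_px += prop.area  # CCL21+ pixels of the component
    return blobs, blob_area_px * upp2, total_area


def ccl21_morphology(ccl21_plane: np.ndarray, asma_plane: np.ndarray,
                     paracortex_mask: np.ndarray, config: AnalysisConfig,
                     calibration: Calibration,
                     cd3_plane: Optional[np.ndarray] = None
                     ) -> Tuple[str, List[CellBlob]]:
    """Classify an LN's CCL21 staining as RETICULAR or IMMUNE_CELL.

    The LN is labeled IMMUNE_CELL when the fraction of CCL21+ area lying in
    aSMA- lymphocyte-shaped blobs reaches ``morphology_blob_fraction``
    (default 0.5).
    """
    blobs, blob_area, total_area = detect_blobs(
        ccl21_plane, asma_plane, cd3_plane, paracortex_mask, config, calibration)
    if total_area <= 0:
        return "RETICULAR", []
    label = "IMMUNE_CELL" if blob_area / total_area >= config.morphology_blob_fraction \
        else "RETICULAR"
    return label, blobs


def cd3_category(blobs: Sequence[CellBlob], vessel: VesselRecord,
                 config: AnalysisConfig, calibration: Calibration) -> str:
    """CD3 co-positivity category of the CCL21+/aSMA- blobs around a vessel.

    Only blobs whose centroid lies within ``cd3_search_um`` of the vessel
    wall count. f = CD3+ fraction: 1 -> "100"; (0.5, 1) -> ">50";
    (0, 0.5] -> "<50"; 0 -> "0". No candidate blobs -> "NA".
    """
    if not blobs:
        return CATEGORY_NA
    ys, xs = np.nonzero(vessel.wall_mask)
    r0, _, c0, _ = vessel.bbox
    wall_xy = np.column_stack([(xs + c0), (ys + r0)]) * calibration.um_per_px
    near = []
    for b in blobs:
        if b.asma_pos or not b.ccl21_pos:
            continue
        d = np.min(np.hypot(wall_xy[:, 0] - b.centroid_um[0],
                            wall_xy[:, 1] - b.centroid_um[1]))
        if d <= config.cd3_search_um:
            near.append(b)
    if not near:
        return CATEGORY_NA
    f = sum(b.cd3_pos for b in near) / len(near)
    if f == 1.0:
        return "100"
    if f > 0.5:
        return ">50"
    if f > 0.0:
        return "<50"
    return "0"


def line_profile(image: MultiplexImage, p0_um: Tuple[float, float],
                 p1_um: Tuple[float, float],
                 channels: Sequence[str]) -> Dict[str, np.ndarray]:
    """Bilinear intensity profiles along a segment (endpoints in µm).

    Samples at 1-px steps; a zero-length segment yields a single sample.
    The returned dict carries one series per channel plus ``distance_um``.
    """
    upp = image.calibration.um_per_px
    h, w = image.shape
    pts = []
    for (x, y) in (p0_um, p1_um):
        col, row = x / upp, y / upp
        if not (0 <= col <= w - 1 and 0 <= row <= h - 1):
            raise ValueError(f"profile endpoint ({x}, {y}) µm outside image")
        pts.append((row, col))
    (r0, c0), (r1, c1) = pts
    length = float(np.hypot(r1 - r0, c1 - c0))
    n = int(np.ceil(length)) + 1
    rows = np.linspace(r0, r1, n)
    cols = np.linspace(c0, c1, n)
    out: Dict[str, np.ndarray] = {
        "distance_um": np.hypot(rows - r0, cols - c0) * upp}
    for ch in channels:
        plane = to_8bit_scale(image.plane(ch))
        out[ch] = ndimage.map_coordinates(plane, [rows, cols], order=1)
    return out
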