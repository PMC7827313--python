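"""HEV detection: PNAd+/Claudin-5+ annuli and their lumens.

Candidate walls are Claudin-5+ components (after a small morphological
closing that seals staining gaps); a component is accepted as an HEV wall
when enough of it lies near PNAd+ signal. Gating at component level keeps
PNAd-discontinuous walls intact as one component, so PNAd coverage can then
be scored on the Claudin-5-defined wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import _geom
from .config import AnalysisConfig
from .imgio import MultiplexImage, ValidationError, to_8bit_scale


@dataclass
class VesselRecord:
    """One segmented HEV and all its derived scores."""

    vessel_id: int
    wall_mask: np.ndarray   # boolean, full frame or crop + offset
    lumen_mask: np.ndarray
    bbox: Tuple[int, int, int, int]  # (row0, row1, col0, col1) of the crop
    centroid_um: Tuple[float, float]  # (x, y)
    border_touching: bool = False
    zone: str = "EXCLUDED"
    diameter_um: float = 0.0
    dilation_class: str = "NON"
    ec_thickness_um: float = float("nan")
    thin_flag: bool = False
    pnad_coverage: float = float("nan")
    pnad_discontinuous: bool = False
    ring_scores: Dict[str, object] = field(default_factory=dict)
    n_blobs: int = 0
    cd3_category: str = "NA"
    wall_area_um2: float = 0.0

    def to_row(self, ln_id: Optional[str] = None) -> dict:
        def _score(marker, attr):
            s = self.ring_scores.get(marker)
            return getattr(s, attr, None) if s is not None else None

        return {
            "ln_id": ln_id, "vessel_id": self.vessel_id,
            "centroid_x_um": self.centroid_um[0],
            "centroid_y_um": self.centroid_um[1],
            "zone": self.zone, "diameter_um": self.diameter_um,
            "dilation_class": self.dilation_class,
            "ec_thickness_um": self.ec_thickness_um, "thin_flag": self.thin_flag,
            "pnad_coverage": self.pnad_coverage,
            "pnad_discontinuous": self.pnad_discontinuous,
            "ccl21_coverage": _score("CCL21", "coverage"),
            "ccl21_category": _score("CCL21", "category"),
            "asma_coverage": _score("ASMA", "coverage"),
            "asma_category": _score("ASMA", "category"),
            "hs_coverage": _score("HS", "coverage"),
            "hs_category": _score("HS", "category"),
            "n_blobs": self.n_blobs, "cd3_category": self.cd3_category,
            "border_touching": self.border_touching,
            "wall_area_um2": self.wall_area_um2,
        }


def detect_hevs(image: MultiplexImage, analysis_mask: np.ndarray,
                config: AnalysisConfig) -> List[VesselRecord]:
    """Segment HEV walls and lumens inside an analysis mask.

    Returns records with geometry fields only (morphometry and scoring are
    separate stages). Vessels whose wall touches the image border are
    flagged; partial annuli bias the diameter estimate.
    """
    for ch in ("PNAD", "CLDN5"):
        if ch not in image:
            raise ValidationError(f"detect_hevs requires channel {ch!r}")
    calib = image.calibration
    upp = calib.um_per_px

    cldn = to_8bit_scale(image.plane("CLDN5"))
    pnad = to_8bit_scale(image.plane("PNAD"))
    cldn_pos = cldn >= config.positivity_threshold("CLDN5", cldn)
    pnad_pos = pnad >= config.positivity_threshold("PNAD", pnad)

    walls = _geom.close_um(cldn_pos, config.wall_closing_um, upp)
    near_pnad = _geom.dilate_um(pnad_pos, config.pnad_gate_dilation_um, upp)

    labels, n = ndimage.label(walls)
    if n == 0:
        return []
    min_wall_px = config.min_wall_area_um2 / calib.um2_per_px2()
    min_lumen_px = config.min_lumen_area_um2 / calib.um2_per_px2()
    h, w = walls.shape

    records: List[VesselRecord] = []
    slices = ndimage.find_objects(labels)
    vid = 0
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        wall = labels[sl] == lab
        area = int(wall.sum())
        if area < min_wall_px:
            continue
        # component-level PNAd gate
        frac = float((wall & near_pnad[sl]).sum()) / area
        if frac < config.pnad_gate_min_fraction:
            continue
        filled = _geom.fill_holes(wall)
        lumen = filled & ~wall
        if lumen.sum() < min_lumen_px:
            lumen = np.zeros_like(lumen)
        ys, xs = np.nonzero(wall)
        cy = float(ys.mean()) + sl[0].start
        cx = float(xs.mean()) + sl[1].start
        ci, cj = int(round(cy)), int(round(cx))
        if not (0 <= ci < h and 0 <= cj < w and analysis_mask[ci, cj]):
            continue
        border = (sl[0].start == 0 or sl[1].start == 0
                  or sl[0].stop == h or sl[1].stop == w)
        records.append(VesselRecord(
            vessel_id=vid,
            wall_mask=wall, lumen_mask=lumen,
            bbox=(sl[0].start, sl[0].stop, sl[1].start, sl[1].stop),
            centroid_um=(cx * upp, cy * upp),
            border_touching=border,
            wall_area_um2=area * calib.um2_per_px2(),
        ))
        vid += 1
    return records


def match_to_truth(records: List[VesselRecord], truth, max_dist_um: float):
    """Greedy nearest-centroid matching between detections and truth rows.

    ``truth`` is a DataFrame with ``center_x_um``/``center_y_um`` columns.
    Ties at equal distance resolve to the lower vessel_id. Returns
    (pairs, unmatched_record_ids, unmatched_truth_indices) where pairs maps
    record vessel_id -> truth index.
    """
    if len(records) == 0 or len(truth) == 0:
        return {}, [r.vessel_id for r in records], list(truth.index)
    det = np.array([r.centroid_um for r in records])
    tru = truth[["center_x_um", "center_y_um"]].to_numpy(float)
    d = np.hypot(det[:, 0:1] - tru[None, :, 0], det[:, 1:2] - tru[None, :, 1])
    pairs = {}
    used_r, used_t = set(), set()
    # stable ordering: by distance, then record id (documented tie-break)
    order = sorted(((d[i, j], records[i].vessel_id, i, j)
                    for i in range(d.shape[0]) for j in range(d.shape[1])))
    for dist, _rid, i, j in order:
        if dist > max_dist_um:
            break
        if i in used_r or j in used_t:
            continue
        pairs[records[i].vessel_id] = truth.index[j]
        used_r.add(i)
        used_t.add(j)
    unmatched_r = [r.vessel_id for i, r in enumerate(records) if i not in used_r]
    unmatched_t = [truth.index[j] for j in range(d.shape[1]) if j not in used_t]
    return pairs, unmatched_r, unmatched_t
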