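"""Analysis regions: tissue, tumor foci, paracortex and per-vessel zones.

The total lymph-node area is the DAPI plane inside a fixed 6–255 intensity
window; tumor cells are the cytokeratin plane inside 35–255 (both on the
8-bit scale, after linear rescaling of 16-bit data). The paracortex is the
CCL21+ reticular area, morphologically closed and hole-filled, minus
everything within the proximity distance (default 200 µm) of the tumor
border or of parenchymal fat. Vessels are zoned by centroid: inside a focus
-> IM; within the proximity distance of a focus -> MA; inside the paracortex
-> PARACORTICAL; otherwise EXCLUDED.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from . import _geom
from .config import AnalysisConfig
from .imgio import Calibration, MultiplexImage, ValidationError, to_8bit_scale

log = logging.getLogger(__name__)


@dataclass
class RegionSet:
    """Masks shared by all per-vessel measurements of one LN section."""

    tissue_mask: np.ndarray
    tumor_mask: np.ndarray
    foci_labels: np.ndarray
    paracortex_mask: np.ndarray
    fat_mask: Optional[np.ndarray] = None
    calibration: Calibration = field(default_factory=lambda: Calibration(0.5))
    #: distance (µm) from each pixel to the nearest tumor pixel
    tumor_distance_um: Optional[np.ndarray] = None

    @property
    def n_foci(self) -> int:
        return int(self.foci_labels.max())


def segment_tissue(dapi_plane: np.ndarray, config: AnalysisConfig,
                   calibration: Calibration) -> np.ndarray:
    """Total LN tissue: DAPI within [dapi_min, dapi_max], filled, despeckled."""
    plane = to_8bit_scale(dapi_plane)
    mask = (plane >= config.dapi_min) & (plane <= config.dapi_max)
    mask = _geom.fill_holes(mask)
    min_px = config.min_tissue_component_um2 / calibration.um2_per_px2()
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        warnings.warn("tissue mask is empty", stacklevel=2)
    return mask


def segment_tumor(ck_plane: np.ndarray, config: AnalysisConfig,
                  tissue_mask: np.ndarray, calibration: Calibration
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Tumor mask and labeled foci from the cytokeratin window.

    Foci are hole-filled before labeling (metastatic tumor cells surround
    vessels, and a vessel enclosed by a focus belongs inside it), and
    components below ``min_focus_area_um2`` are discarded — isolated
    suprathreshold pixels are noise, not metastases.
    """
    plane = to_8bit_scale(ck_plane)
    mask = (plane >= config.ck_min) & (plane <= config.ck_max) & tissue_mask
    filled = _geom.fill_holes(mask)
    labels, n = ndimage.label(filled)
    if n:
        min_px = config.min_focus_area_um2 / calibration.um2_per_px2()
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        filled = np.isin(labels, keep)
        labels, _ = ndimage.label(filled)
        mask &= filled
    return mask, labels


def metastatic_burden(region_set: RegionSet) -> float:
    """Tumor area as a percentage of total LN tissue area; NaN if no tissue."""
    tissue_px = int(region_set.tissue_mask.sum())
    if tissue_px == 0:
        warnings.warn("empty tissue mask: metastatic burden undefined", stacklevel=2)
        return float("nan")
    tumor_px = int((region_set.tumor_mask & region_set.tissue_mask).sum())
    return 100.0 * tumor_px / tissue_px


def paracortex_mask(ccl21_plane: np.ndarray, tissue_mask: np.ndarray,
                    tumor_mask: np.ndarray, config: AnalysisConfig,
                    calibration: Calibration,
                    fat_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """CCL21-defined paracortex with tumor/fat proximity exclusion.

    The CCL21+ reticular mesh is thresholded, closed (to bridge the mesh
    into a solid region) and hole-filled, then everything within
    ``proximity_um`` of the tumor border or of fat is removed.
    """
    if ccl21_plane is None:
        raise ValidationError("paracortex requires a CCL21 plane")
    upp = calibration.um_per_px
    plane = to_8bit_scale(ccl21_plane)
    thr = config.positivity_threshold("CCL21", plane[tissue_mask]
                                      if tissue_mask.any() else plane)
    pos = (plane >= thr) & tissue_mask
    if not pos.any():
        return np.zeros_like(tissue_mask)
    mesh = _geom.close_um(pos, config.paracortex_closing_um, upp)
    mesh = _geom.fill_holes(mesh)
    excl = np.zeros_like(tissue_mask)
    if tumor_mask.any():
        excl |= _geom.dilate_um(tumor_mask, config.proximity_um, upp)
    if fat_mask is not None and fat_mask.any():
        excl |= _geom.dilate_um(fat_mask, config.proximity_um, upp)
    return mesh & tissue_mask & ~excl


def build_regions(image: MultiplexImage, config: AnalysisConfig,
                  fat_mask: Optional[np.ndarray] = None) -> RegionSet:
    """Run the full region stage on one multiplex image."""
    calib = image.calibration
    tissue = segment_tissue(image.plane("DAPI"), config, calib)
    if "CK" in image:
        tumor, foci = segment_tumor(image.plane("CK"), config, tissue, calib)
    else:
        tumor = np.zeros_like(tissue)
        foci = np.zeros(tissue.shape, np.int32)
    para = paracortex_mask(image.plane("CCL21"), tissue, tumor, config, calib,
                           fat_mask=fat_mask)
    tumor_filled = foci > 0
    if tumor_filled.any():
        dist = ndimage.distance_transform_edt(~tumor_filled) * calib.um_per_px
    else:
        dist = np.full(tissue.shape, np.inf)
    return RegionSet(tissue_mask=tissue, tumor_mask=tumor, foci_labels=foci,
                     paracortex_mask=para, fat_mask=fat_mask, calibration=calib,
                     tumor_distance_um=dist)


def zone_of(vessel_centroid_um: Tuple[float, float], region_set: RegionSet,
            config: AnalysisConfig) -> str:
    """Zone label for a vessel centroid (µm coordinates, x then y)."""
    upp = region_set.calibration.um_per_px
    x, y = vessel_centroid_um
    j, i = int(round(x / upp)), int(round(y / upp))
    h, w = region_set.tissue_mask.shape
    if not (0 <= i < h and 0 <= j < w):
        return "EXCLUDED"
    if region_set.foci_labels[i, j] > 0:
        return "IM"
    if region_set.tumor_distance_um is not None and \
            region_set.tumor_distance_um[i, j] <= config.proximity_um:
        return "MA"
    if region_set.paracortex_mask[i, j]:
        return "PARACORTICAL"
    return "EXCLUDED"
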