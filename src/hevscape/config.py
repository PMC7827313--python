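"""Analysis configuration: every numeric rule of the HEV remodeling scheme.

All length thresholds are in micrometres; intensity bounds are on the 8-bit
(0–255) scale used by the tissue/tumor area rules. 16-bit input planes are
linearly rescaled to 8-bit before these bounds apply (see
:func:`hevscape.imgio.to_8bit_scale`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and tunables of the whole pipeline.

    Attributes
    ----------
    dilation_high_um:
        Lumen-diameter cutoff between intermediately and highly dilated
        vessels. Diameters >= this value classify as HIGH (the boundary is
        assigned upward; configurable via this field).
    proximity_um:
        Tumor/fat exclusion and metastasis-association distance.
    dapi_min, dapi_max:
        Intensity window defining total lymph-node tissue on the DAPI plane.
    ck_min, ck_max:
        Intensity window defining tumor cells on the cytokeratin plane.
    ring_width_um:
        Width of the perivascular scoring ring outside the vessel wall.
    coverage_continuous_min, coverage_none_max:
        Angular-coverage cutoffs mapping a fraction to the
        CONTINUOUS / PARTIAL / NONE categories.
    pnad_discontinuous_max, pnad_min_gap_um:
        A wall is PNAd-discontinuous when its coverage is below
        ``pnad_discontinuous_max`` AND the longest contiguous negative arc is
        at least ``pnad_min_gap_um`` long.
    thin_ec_um:
        Mean endothelial width below which the wall is flagged thin.
    """

    # dilation classes
    dilation_high_um: float = 10.0
    # zoning / exclusion
    proximity_um: float = 200.0
    # tissue / tumor intensity windows (8-bit scale)
    dapi_min: float = 6.0
    dapi_max: float = 255.0
    ck_min: float = 35.0
    ck_max: float = 255.0
    min_tissue_component_um2: float = 1000.0
    min_focus_area_um2: float = 200.0
    # paracortex construction
    paracortex_closing_um: float = 25.0
    # perivascular scoring
    ring_width_um: float = 10.0
    coverage_continuous_min: float = 0.80
    coverage_none_max: float = 0.10
    n_angular_bins: int = 72
    min_positive_px_per_bin: int = 2
    # PNAd continuity
    pnad_discontinuous_max: float = 0.90
    pnad_min_gap_um: float = 10.0
    # endothelium
    thin_ec_um: float = 3.0
    # vessel detection
    wall_closing_um: float = 2.0
    min_wall_area_um2: float = 50.0
    min_lumen_area_um2: float = 5.0
    pnad_gate_dilation_um: float = 2.0
    pnad_gate_min_fraction: float = 0.10
    # lymphocyte blob detection
    blob_min_area_um2: float = 20.0
    blob_max_area_um2: float = 120.0
    blob_min_circularity: float = 0.6
    morphology_blob_fraction: float = 0.5
    cd3_search_um: float = 25.0
    # channel positivity: Otsu per plane unless overridden; never below floor
    positivity_floor: float = 20.0
    positivity_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_none_max < self.coverage_continuous_min <= 1.0):
            raise ValueError(
                "require 0 <= coverage_none_max < coverage_continuous_min <= 1, "
                f"got {self.coverage_none_max}/{self.coverage_continuous_min}"
            )
        for name in ("dilation_high_um", "proximity_um", "ring_width_um",
                     "thin_ec_um", "wall_closing_um", "pnad_min_gap_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("dapi_min", "dapi_max", "ck_min", "ck_max"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255], got {v}")

    def positivity_threshold(self, channel: str, plane) -> float:
        """Positivity cutoff for a channel: override, else Otsu with a floor."""
        if channel in self.positivity_overrides:
            return float(self.positivity_overrides[channel])
        from skimage.filters import threshold_otsu
        import numpy as np

        arr = np.asarray(plane, dtype=float)
        if arr.max() <= arr.min():
            return self.positivity_floor
        return max(float(threshold_otsu(arr)), self.positivity_floor)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**(data.get("analysis", data) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"analysis": self.to_dict()}, fh, sort_keys=False)


def load_config(path: Optional[str] = None) -> AnalysisConfig:
    """Config from YAML path, or defaults when *path* is None."""
    if path is None:
        return AnalysisConfig()
    return AnalysisConfig.from_yaml(path)
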