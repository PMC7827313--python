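"""Synthetic multiplex lymph-node images with exhaustive ground truth.

The generator emulates the structures the pipeline measures: PNAd+/Claudin-5+
high endothelial venules rendered as elliptical annuli with controllable lumen
diameter, wall thickness and perimeter marker coverage; a CCL21+/aSMA+
reticular paracortex; cytokeratin+ metastatic foci with dense DAPI;
CCL21-coated lymphocyte blobs with partial CD3 co-staining; and additive
Gaussian noise. Every sampled quantity is recorded in a truth table so the
whole analysis, and its parameter-recovery tests, run without patient data.

Packaged group profiles (``profiles/*.yaml``) encode printed group-level
fractions of the four study groups (cancer-free organ donors, DCIS, invasive
carcinoma without and with nodal metastasis) as generative probabilities.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import _geom
from .imgio import (CHANNELS, Calibration, ChannelMap, MultiplexImage,
                    write_multiplex)

CLASSES = ("NON", "INT", "HIGH")
CATEGORIES = ("CONTINUOUS", "PARTIAL", "NONE")
ZONES = ("PARACORTICAL", "MA", "IM", "EXCLUDED")
RING_MARKERS = ("CCL21", "ASMA", "HS")


class GenerationError(RuntimeError):
    """Raised when vessels cannot be placed inside the tissue disc."""


class ConfigurationError(ValueError):
    """Raised for invalid group profiles."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class VesselSpec:
    """Generative description of one vessel; serializes losslessly to truth.

    ``lumen_axes`` are the lumen semi-axes (a >= b >= 0) in micrometres;
    b = 0 encodes a closed (non-dilated) lumen. The shortest lumen diameter
    is 2*b by construction.
    """

    lumen_axes: Tuple[float, float]
    wall_thickness: float
    pnad_coverage: float
    ring_coverage: Dict[str, float]
    ring_category: Dict[str, str]
    dilation_class: str
    thin: bool
    pnad_discontinuous: bool
    n_ccl21_cells: int = 0
    cd3_fraction: float = 0.0
    zone: str = "PARACORTICAL"
    center: Optional[Tuple[float, float]] = None  # µm, image frame
    theta: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.lumen_axes
        if not (a >= b >= 0):
            raise ConfigurationError(f"lumen axes must satisfy a >= b >= 0, got {a}, {b}")
        if self.wall_thickness <= 0:
            raise ConfigurationError("wall_thickness must be > 0")
        for name, v in [("pnad_coverage", self.pnad_coverage),
                        ("cd3_fraction", self.cd3_fraction),
                        *self.ring_coverage.items()]:
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"coverage {name} outside [0,1]: {v}")
        if self.n_ccl21_cells < 0:
            raise ConfigurationError("n_ccl21_cells must be >= 0")

    @property
    def outer_axes(self) -> Tuple[float, float]:
        a, b = self.lumen_axes
        return a + self.wall_thickness, b + self.wall_thickness

    @property
    def r_out(self) -> float:
        """Bounding circle radius of the wall, µm."""
        return self.outer_axes[0]

    @property
    def shortest_lumen_diameter(self) -> float:
        return 2.0 * self.lumen_axes[1]


@dataclass
class Metastasis:
    """Metastatic-focus block of a group profile."""

    n_foci: int = 1
    focus_radius_um: Tuple[float, float] = (65.0, 85.0)
    ma_per_focus: float = 12.0
    im_per_focus: float = 5.0
    p_ccl21_none_im: float = 0.87
    p_ccl21_none_ma: float = 0.35
    p_class_ma: Optional[Dict[str, float]] = None
    p_class_im: Optional[Dict[str, float]] = None


@dataclass
class GroupProfile:
    """Generative parameters of one patient group."""

    name: str
    lns: int
    vessels_per_ln: float
    p_class: Dict[str, float]
    diameter_range_by_class: Dict[str, Tuple[float, float]]
    p_thin_by_class: Dict[str, float]
    p_pnad_discont_by_class: Dict[str, float]
    ccl21_score_probs_by_class: Dict[str, Dict[str, float]]
    asma_score_probs: Dict[str, float]
    hs_loss_probs_by_class: Dict[str, Dict[str, float]]
    p_lymphocyte_phenotype: float
    cd3_category_probs: Dict[str, float] = field(
        default_factory=lambda: {"100": 0.4, ">50": 0.3, "<50": 0.2, "0": 0.1})
    metastasis: Optional[Metastasis] = None
    image_px: int = 1792
    um_per_px: float = 0.5
    noise_sd: float = 8.0  # 8-bit units; ~5% of the wall foreground amplitude

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _check_probs(d, label):
            s = sum(d.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(f"{label} probabilities sum to {s}, not 1")
            if any(v < 0 for v in d.values()):
                raise ConfigurationError(f"{label} has negative probability")

        _check_probs(self.p_class, f"{self.name}: p_class")
        for cls, probs in self.ccl21_score_probs_by_class.items():
            _check_probs(probs, f"{self.name}: ccl21[{cls}]")
        for cls, probs in self.hs_loss_probs_by_class.items():
            _check_probs(probs, f"{self.name}: hs[{cls}]")
        _check_probs(self.asma_score_probs, f"{self.name}: asma")
        _check_probs(self.cd3_category_probs, f"{self.name}: cd3")
        # diameter ranges must be disjoint and respect the 10 µm class rule
        rng_int = self.diameter_range_by_class.get("INT")
        rng_high = self.diameter_range_by_class.get("HIGH")
        for label, rng in (("INT", rng_int), ("HIGH", rng_high)):
            if rng is None or rng[1] < rng[0]:
                raise ConfigurationError(f"{self.name}: empty diameter range for {label}")
        if not (0 < rng_int[0] and rng_int[1] < 10.0 <= rng_high[0]):
            raise ConfigurationError(
                f"{self.name}: diameter ranges must satisfy 0 < INT < 10 <= HIGH, "
                f"got INT={rng_int}, HIGH={rng_high}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GroupProfile":
        data = dict(data)
        met = data.get("metastasis")
        if met is not None and not isinstance(met, Metastasis):
            met = Metastasis(**{k: tuple(v) if k == "focus_radius_um" else v
                                for k, v in met.items()})
        data["metastasis"] = met
        data["diameter_range_by_class"] = {
            k: tuple(v) for k, v in data["diameter_range_by_class"].items()}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "GroupProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


PACKAGED_PROFILES = ("od", "dcis", "idc_met_neg", "idc_met_pos")


def load_profile(name_or_path) -> GroupProfile:
    """Load a packaged profile by short name, or any profile YAML by path."""
    p = Path(str(name_or_path))
    if p.exists():
        return GroupProfile.from_yaml(p)
    stem = p.stem
    if stem in PACKAGED_PROFILES:
        ref = resources.files("hevscape").joinpath(f"profiles/{stem}.yaml")
        with resources.as_file(ref) as fp:
            return GroupProfile.from_yaml(fp)
    raise ConfigurationError(
        f"profile {name_or_path!r} is neither a file nor one of {PACKAGED_PROFILES}")


# ---------------------------------------------------------------------------
# vessel sampling


def _draw_category(probs: Dict[str, float], rng: np.random.Generator) -> str:
    names = list(probs)
    return names[rng.choice(len(names), p=np.array([probs[n] for n in names]))]


def _coverage_for_category(cat: str, rng: np.random.Generator) -> float:
    if cat == "NONE":
        return float(rng.uniform(0.0, 0.04))
    if cat == "PARTIAL":
        return float(rng.uniform(0.35, 0.65))
    return float(rng.uniform(0.93, 1.0))


_CD3_FRACTION_RANGES = {"100": (1.0, 1.0), ">50": (0.55, 0.9),
                        "<50": (0.1, 0.45), "0": (0.0, 0.0)}

#: wall-thickness draws, µm (thin endothelium vs. normal cuboidal wall)
THIN_WALL_UM = (2.2, 2.8)
NORMAL_WALL_UM = (4.0, 6.0)
#: slit semi-length of a closed (non-dilated) lumen, µm
NON_SLIT_UM = (6.0, 10.0)
ASPECT_RANGE = (1.0, 1.6)


def sample_vessel(profile: GroupProfile, class_label: str,
                  rng: np.random.Generator, zone: str = "PARACORTICAL",
                  ccl21_probs: Optional[Dict[str, float]] = None) -> VesselSpec:
    """Draw one vessel's generative parameters for a dilation class.

    The returned spec's shortest lumen diameter (2*b) lies inside the
    profile's diameter range for the class; coverages and flags are drawn
    from the profile's per-class category probabilities. ``ccl21_probs``
    overrides the perivascular-CCL21 category probabilities (used for
    metastasis-associated and intrametastatic vessels).
    """
    if class_label not in CLASSES:
        raise ConfigurationError(f"unknown dilation class {class_label!r}")

    thin = bool(rng.random() < profile.p_thin_by_class.get(class_label, 0.0))
    t = float(rng.uniform(*(THIN_WALL_UM if thin else NORMAL_WALL_UM)))

    if class_label == "NON":
        a, b = float(rng.uniform(*NON_SLIT_UM)), 0.0
    else:
        lo, hi = profile.diameter_range_by_class[class_label]
        if hi < lo:
            raise ConfigurationError(f"empty diameter range for {class_label}")
        b = float(rng.uniform(lo, hi)) / 2.0
        a = b * float(rng.uniform(*ASPECT_RANGE))

    discont = bool(rng.random() < profile.p_pnad_discont_by_class.get(class_label, 0.0))
    if discont:
        # contiguous negative arc of at least ~14 µm at the wall mid-radius
        mid_perim = _geom.ellipse_perimeter_um(a + t / 2, b + t / 2)
        cov = float(rng.uniform(0.55, 0.80))
        cov = min(cov, 1.0 - 14.0 / mid_perim) if mid_perim > 14.0 else cov
        pnad_cov = max(cov, 0.05)
    else:
        pnad_cov = 1.0

    probs_ccl21 = ccl21_probs or profile.ccl21_score_probs_by_class[class_label]
    cats = {
        "CCL21": _draw_category(probs_ccl21, rng),
        "ASMA": _draw_category(profile.asma_score_probs, rng),
        "HS": _draw_category(profile.hs_loss_probs_by_class[class_label], rng),
    }
    covs = {m: _coverage_for_category(c, rng) for m, c in cats.items()}

    cd3_cat = _draw_category(profile.cd3_category_probs, rng)
    lo, hi = _CD3_FRACTION_RANGES[cd3_cat]
    cd3_fraction = float(rng.uniform(lo, hi)) if hi > lo else lo

    return VesselSpec(
        lumen_axes=(a, b), wall_thickness=t, pnad_coverage=pnad_cov,
        ring_coverage=covs, ring_category=cats, dilation_class=class_label,
        thin=thin, pnad_discontinuous=discont, cd3_fraction=cd3_fraction,
        zone=zone, theta=float(rng.uniform(0, np.pi)),
    )


def _met_probs(p_none: float) -> Dict[str, float]:
    rest = 1.0 - p_none
    return {"CONTINUOUS": 0.3 * rest, "PARTIAL": 0.7 * rest, "NONE": p_none}


# ---------------------------------------------------------------------------
# layout and rendering


@dataclass
class Focus:
    center: Tuple[float, float]  # µm
    radius: float


@dataclass
class BlobSpec:
    center: Tuple[float, float]  # µm
    radius: float
    cd3_pos: bool
    asma_pos: bool = False
    parent_vessel: Optional[int] = None


@dataclass
class LNLayout:
    """Geometry of one synthetic lymph node section."""

    field_px: int
    um_per_px: float
    tissue_radius_um: float
    foci: List[Focus] = field(default_factory=list)
    fat: List[Focus] = field(default_factory=list)  # fat patches as discs
    mesh_spacing_um: float = 18.0
    mesh_width_um: float = 1.0
    mesh_phase: Tuple[float, float] = (0.0, 0.0)
    phenotype: bool = False
    scattered_blob_density_per_mm2: float = 0.0

    def mesh_clearance_um(self, x_um: float, y_um: float) -> float:
        """Approximate distance (µm) from a point to the nearest mesh line."""
        upp = self.um_per_px
        s = max(round(self.mesh_spacing_um / upp), 2)
        w = max(round(self.mesh_width_um / upp), 1)
        xp, yp = x_um / upp, y_um / upp
        jx = 3.0 * np.sin(yp * 0.05 + self.mesh_phase[0])
        jy = 3.0 * np.sin(xp * 0.043 + self.mesh_phase[1])
        rx = float(np.mod(xp + jx, s))
        ry = float(np.mod(yp + jy, s))
        dx = 0.0 if rx < w else min(rx - w, s - rx)
        dy = 0.0 if ry < w else min(ry - w, s - ry)
        return min(dx, dy) * upp

    @property
    def center_um(self) -> Tuple[float, float]:
        c = self.field_px * self.um_per_px / 2.0
        return (c, c)


#: rendered 8-bit-scale intensities per structure
STYLE = {
    "dapi_tissue": 40.0, "dapi_focus_extra": 50.0,
    "cldn5_wall": 160.0, "pnad_wall": 180.0,
    "ccl21_mesh": 120.0, "ccl21_arc": 140.0,
    "ccl21_blob_rim": 150.0, "ccl21_blob_interior": 100.0,
    "asma_mesh": 110.0, "asma_arc": 130.0, "asma_blob": 130.0,
    "hs_mesh": 100.0, "hs_arc": 135.0,
    "ck_focus": 150.0, "cd3_blob": 140.0,
    "arc_width_um": 2.0,
}

#: blob geometry: lymphocytes as discs with surface (rim) CCL21
BLOB_RADIUS_UM = (3.2, 4.5)
BLOB_RIM_UM = 1.25
#: radial band (µm beyond the wall) where vessel-attached blobs live; kept
#: outside the 10 µm marker-scoring ring on purpose
BLOB_BAND_UM = (12.0, 25.0)
MIN_WALL_GAP_UM = 13.0  # minimum wall-to-wall separation between vessels


def _ellipse_radius_at(a: float, b: float, phi: np.ndarray) -> np.ndarray:
    """Radius of an ellipse boundary at polar angle phi (vessel frame)."""
    return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)


def render_ln_image(specs: Sequence[VesselSpec], layout: LNLayout,
                    calib: Optional[Calibration] = None, noise_sd: float = 0.0,
                    rng: Optional[np.random.Generator] = None,
                    blobs: Optional[List[BlobSpec]] = None,
                    ln_id: str = "ln") -> Tuple[MultiplexImage, Dict[str, np.ndarray], pd.DataFrame]:
    """Rasterize vessels, stroma, tumor foci and lymphocyte blobs.

    All specs must have centers assigned (see :func:`generate_ln` for
    placement). Returns the multichannel image (uint16, 8-bit-scale values
    stored as value*257), the noise-free structure masks, and the per-vessel
    truth table.
    """
    rng = rng or np.random.default_rng(0)
    calib = calib or Calibration(um_per_px=layout.um_per_px)
    upp = calib.um_per_px
    n = layout.field_px
    shape = (n, n)
    planes = {c: np.zeros(shape, np.float32) for c in CHANNELS}

    def px(v):  # µm -> px
        return v / upp

    cx0, cy0 = layout.center_um
    yy, xx = np.mgrid[0:n, 0:n]
    rr2 = (xx - px(cx0)) ** 2 + (yy - px(cy0)) ** 2
    tissue = rr2 <= px(layout.tissue_radius_um) ** 2

    foci_mask = np.zeros(shape, bool)
    for f in layout.foci:
        foci_mask |= _geom.ellipse_mask(shape, (px(f.center[0]), px(f.center[1])),
                                        px(f.radius), px(f.radius))
    fat_mask = np.zeros(shape, bool)
    for f in layout.fat:
        fat_mask |= _geom.ellipse_mask(shape, (px(f.center[0]), px(f.center[1])),
                                       px(f.radius), px(f.radius))

    planes["DAPI"][tissue] = STYLE["dapi_tissue"]
    planes["DAPI"][foci_mask] += STYLE["dapi_focus_extra"]

    # --- vessels -----------------------------------------------------------
    wall_all = np.zeros(shape, bool)
    lumen_all = np.zeros(shape, bool)
    vessel_core = np.zeros(shape, bool)  # wall + margin, excluded from CK
    clearance = np.zeros(shape, bool)  # stromal mesh keep-out around vessels
    arc_w = STYLE["arc_width_um"]
    rows = []
    for vid, s in enumerate(specs):
        if s.center is None:
            raise GenerationError(f"vessel {vid} has no center assigned")
        a, b = s.lumen_axes
        t = s.wall_thickness
        cxp, cyp = px(s.center[0]), px(s.center[1])
        clr_um = a + t + (31.0 + BLOB_RADIUS_UM[1] if s.n_ccl21_cells > 0
                          else 10.0 + 4.0)
        pad = px(clr_um) + 2
        x0, x1 = max(0, int(cxp - pad)), min(n, int(cxp + pad) + 2)
        y0, y1 = max(0, int(cyp - pad)), min(n, int(cyp + pad) + 2)
        if x0 >= x1 or y0 >= y1:
            raise GenerationError(f"vessel {vid} rasterized outside the frame")
        sub = (slice(y0, y1), slice(x0, x1))
        lyy, lxx = np.mgrid[y0:y1, x0:x1]
        xr = (lxx - cxp) * np.cos(s.theta) + (lyy - cyp) * np.sin(s.theta)
        yr = -(lxx - cxp) * np.sin(s.theta) + (lyy - cyp) * np.cos(s.theta)

        def _ell(a_um, b_um):
            if a_um <= 0 or b_um <= 0:
                return np.zeros(xr.shape, bool)
            return (xr / px(a_um)) ** 2 + (yr / px(b_um)) ** 2 <= 1.0

        outer = _ell(a + t, b + t)
        lumen = _ell(a, b)
        wall = outer & ~lumen
        ang = np.mod(np.arctan2(yr, xr), 2 * np.pi)

        planes["CLDN5"][sub][wall] = STYLE["cldn5_wall"]
        # PNAd on a contiguous fraction of the wall (one gap)
        pn_arc = _geom.arc_mask(ang, rng.uniform(0, 2 * np.pi), s.pnad_coverage)
        planes["PNAD"][sub][wall & pn_arc] = STYLE["pnad_wall"]

        # perivascular marker bands just outside the wall
        band = _ell(a + t + arc_w, b + t + arc_w) & ~outer
        for marker, chan, inten in (("CCL21", "CCL21", STYLE["ccl21_arc"]),
                                    ("ASMA", "ASMA", STYLE["asma_arc"]),
                                    ("HS", "HS", STYLE["hs_arc"])):
            cov = s.ring_coverage.get(marker, 0.0)
            if cov <= 0:
                continue
            m_arc = _geom.arc_mask(ang, rng.uniform(0, 2 * np.pi), cov)
            planes[chan][sub][band & m_arc] = inten

        wall_all[sub] |= wall
        lumen_all[sub] |= lumen
        vessel_core[sub] |= _ell(a + t + 3.0, b + t + 3.0)
        rd2 = (lxx - cxp) ** 2 + (lyy - cyp) ** 2
        clearance[sub] |= rd2 <= px(clr_um) ** 2

        rows.append({
            "ln_id": ln_id, "vessel_id": vid,
            "center_x_um": s.center[0], "center_y_um": s.center[1],
            "true_class": s.dilation_class,
            "true_diameter_um": s.shortest_lumen_diameter,
            "true_wall_thickness_um": s.wall_thickness,
            "true_thin": s.thin,
            "true_pnad_coverage": s.pnad_coverage,
            "true_pnad_discontinuous": s.pnad_discontinuous,
            "true_ccl21_coverage": s.ring_coverage.get("CCL21", np.nan),
            "true_ccl21_category": s.ring_category.get("CCL21"),
            "true_asma_coverage": s.ring_coverage.get("ASMA", np.nan),
            "true_asma_category": s.ring_category.get("ASMA"),
            "true_hs_coverage": s.ring_coverage.get("HS", np.nan),
            "true_hs_category": s.ring_category.get("HS"),
            "true_zone": s.zone,
            "true_n_blobs": s.n_ccl21_cells,
            "true_cd3_fraction": s.cd3_fraction,
        })

    # --- tumor foci (cytokeratin), tumor cells surround the vessels --------
    ck = foci_mask & ~vessel_core
    planes["CK"][ck] = STYLE["ck_focus"]

    # --- reticular stroma (CCL21 / aSMA / HS mesh) -------------------------
    mesh_region = (
        _geom.erode_um(tissue, 6.0, upp)
        & ~_geom.dilate_um(foci_mask, 4.0, upp)
        & ~(_geom.dilate_um(fat_mask, 4.0, upp) if fat_mask.any() else fat_mask)
        & ~clearance
    )
    s_px = max(round(px(layout.mesh_spacing_um)), 2)
    w_px = max(round(px(layout.mesh_width_um)), 1)
    jx = 3.0 * np.sin(yy * 0.05 + layout.mesh_phase[0])
    jy = 3.0 * np.sin(xx * 0.043 + layout.mesh_phase[1])
    mesh = ((np.mod(xx + jx, s_px) < w_px) | (np.mod(yy + jy, s_px) < w_px))
    mesh &= mesh_region
    planes["CCL21"][mesh] = STYLE["ccl21_mesh"]
    planes["ASMA"][mesh] = STYLE["asma_mesh"]
    planes["HS"][mesh] = STYLE["hs_mesh"]

    # --- lymphocyte blobs: CCL21 on the rim, CD3 in the interior -----------
    blob_mask = np.zeros(shape, bool)
    for bl in (blobs or []):
        cxp, cyp = px(bl.center[0]), px(bl.center[1])
        pad = px(bl.radius) + 2
        x0, x1 = max(0, int(cxp - pad)), min(n, int(cxp + pad) + 2)
        y0, y1 = max(0, int(cyp - pad)), min(n, int(cyp + pad) + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = (slice(y0, y1), slice(x0, x1))
        lyy, lxx = np.mgrid[y0:y1, x0:x1]
        rd2 = (lxx - cxp) ** 2 + (lyy - cyp) ** 2
        disc = rd2 <= px(bl.radius) ** 2
        interior = rd2 <= px(max(bl.radius - BLOB_RIM_UM, 0.0)) ** 2
        planes["CCL21"][sub][disc & ~interior] = STYLE["ccl21_blob_rim"]
        planes["CCL21"][sub][interior] = STYLE["ccl21_blob_interior"]
        if bl.cd3_pos:
            planes["CD3"][sub][interior] = STYLE["cd3_blob"]
        if bl.asma_pos:
            planes["ASMA"][sub][interior] = STYLE["asma_blob"]
        blob_mask[sub] |= disc

    masks = {
        "tissue": tissue, "tumor": ck, "foci": foci_mask, "fat": fat_mask,
        "wall": wall_all, "lumen": lumen_all, "mesh": mesh, "blobs": blob_mask,
    }

    truth = pd.DataFrame(rows)

    # --- noise and quantization -------------------------------------------
    out = {}
    for c in CHANNELS:
        arr = planes[c]
        if noise_sd > 0:
            arr = arr + noise_sd * rng.standard_normal(shape, dtype=np.float32)
        arr = np.clip(arr, 0.0, 255.0)
        out[c] = np.round(arr * 257.0).astype(np.uint16)

    image = MultiplexImage(planes=out, calibration=calib)
    return image, masks, truth


# ---------------------------------------------------------------------------
# whole-LN generation (placement + rendering)


@dataclass
class LNSample:
    ln_id: str
    image: MultiplexImage
    masks: Dict[str, np.ndarray]
    truth: pd.DataFrame
    ln_truth: dict
    layout: LNLayout
    specs: List[VesselSpec]
    blobs: List[BlobSpec]


def _sample_layout(profile: GroupProfile, rng: np.random.Generator) -> LNLayout:
    field_um = profile.image_px * profile.um_per_px
    tissue_r = 0.47 * field_um
    phenotype = bool(rng.random() < profile.p_lymphocyte_phenotype)
    layout = LNLayout(
        field_px=profile.image_px, um_per_px=profile.um_per_px,
        tissue_radius_um=tissue_r,
        mesh_spacing_um=60.0 if phenotype else 18.0,
        mesh_phase=(float(rng.uniform(0, 2 * np.pi)),
                    float(rng.uniform(0, 2 * np.pi))),
        phenotype=phenotype,
        scattered_blob_density_per_mm2=800.0 if phenotype else 0.0,
    )
    met = profile.metastasis
    if met is not None:
        cx0, cy0 = layout.center_um
        angles = rng.uniform(0, 2 * np.pi) + np.arange(met.n_foci) * (2 * np.pi / max(met.n_foci, 1))
        for ang in angles:
            r_f = float(rng.uniform(*met.focus_radius_um))
            d = float(rng.uniform(0.60, 0.80)) * (tissue_r - r_f - 30.0)
            layout.foci.append(Focus(
                center=(cx0 + d * np.cos(ang), cy0 + d * np.sin(ang)), radius=r_f))
    return layout


def generate_ln(profile: GroupProfile, rng: np.random.Generator,
                ln_id: str = "ln0") -> LNSample:
    """Sample vessels for one LN, place them, and render the image."""
    layout = _sample_layout(profile, rng)
    cx0, cy0 = layout.center_um
    met = profile.metastasis

    # -- draw vessel specs per zone
    specs: List[VesselSpec] = []
    n_para = int(round(profile.vessels_per_ln))
    class_names = list(profile.p_class)
    p = np.array([profile.p_class[c] for c in class_names])
    for _ in range(n_para):
        cls = class_names[rng.choice(len(class_names), p=p)]
        specs.append(sample_vessel(profile, cls, rng, zone="PARACORTICAL"))
    if met is not None:
        for f in layout.foci:
            for zone, mean_n, p_cls, p_none in (
                    ("MA", met.ma_per_focus, met.p_class_ma, met.p_ccl21_none_ma),
                    ("IM", met.im_per_focus, met.p_class_im, met.p_ccl21_none_im)):
                probs = p_cls or profile.p_class
                names = list(probs)
                pv = np.array([probs[c] for c in names])
                # cap at what the focus can geometrically host
                cap = 6 if zone == "IM" else 25
                for _ in range(min(int(rng.poisson(mean_n)), cap)):
                    cls = names[rng.choice(len(names), p=pv)]
                    specs.append(sample_vessel(profile, cls, rng, zone=zone,
                                               ccl21_probs=_met_probs(p_none)))

    # -- phenotype LNs carry CCL21+ lymphocyte blobs around dilated vessels
    if layout.phenotype:
        for s in specs:
            if s.zone != "PARACORTICAL":
                continue
            if s.dilation_class == "HIGH":
                s.n_ccl21_cells = int(rng.poisson(18))
            elif s.dilation_class == "INT":
                s.n_ccl21_cells = int(rng.poisson(8))
    else:
        for s in specs:
            if s.zone == "PARACORTICAL" and s.dilation_class == "HIGH":
                s.n_ccl21_cells = int(rng.random() < 0.4)

    # -- placement ----------------------------------------------------------
    # Vessels are placed largest-first by rejection sampling. A failed
    # paracortical placement restarts the whole placement (fresh positions,
    # same specs: retries never change the class mix driving the dilated
    # fractions) before giving up. An unplaceable MA/IM vessel is dropped
    # with a warning instead: its focus is simply full, and the CCL21
    # category is drawn independently of vessel geometry, so the zone
    # CCL21 fractions are unaffected by which vessels fit.
    def _place_all():
        placed: List[Tuple[float, float, float]] = []  # (x, y, r_out)
        kept: List[int] = []

        def _far_enough(x, y, r_out):
            for (px_, py_, pr) in placed:
                if (x - px_) ** 2 + (y - py_) ** 2 < \
                        (r_out + pr + MIN_WALL_GAP_UM) ** 2:
                    return False
            return True

        order = sorted(range(len(specs)), key=lambda i: -specs[i].r_out)
        for i in order:
            s = specs[i]
            r_out = s.r_out
            ok = False
            for _try in range(500):
                if s.zone == "PARACORTICAL":
                    r_max = layout.tissue_radius_um - r_out - 45.0
                    rr = r_max * np.sqrt(rng.random())
                    aa = rng.uniform(0, 2 * np.pi)
                    x, y = cx0 + rr * np.cos(aa), cy0 + rr * np.sin(aa)
                    if any(np.hypot(x - f.center[0], y - f.center[1])
                           < f.radius + 200.0 + 25.0 for f in layout.foci):
                        continue
                elif s.zone == "MA":
                    f = layout.foci[int(rng.integers(len(layout.foci)))]
                    rr = rng.uniform(f.radius + r_out + 8.0, f.radius + 175.0)
                    aa = rng.uniform(0, 2 * np.pi)
                    x, y = f.center[0] + rr * np.cos(aa), f.center[1] + rr * np.sin(aa)
                    if np.hypot(x - cx0, y - cy0) > \
                            layout.tissue_radius_um - r_out - 45.0:
                        continue
                else:  # IM
                    f = layout.foci[int(rng.integers(len(layout.foci)))]
                    r_max = f.radius - r_out - 6.0
                    if r_max <= 0:
                        continue
                    rr = r_max * np.sqrt(rng.random())
                    aa = rng.uniform(0, 2 * np.pi)
                    x, y = f.center[0] + rr * np.cos(aa), f.center[1] + rr * np.sin(aa)
                if _far_enough(x, y, r_out):
                    s.center = (float(x), float(y))
                    placed.append((x, y, r_out))
                    kept.append(i)
                    ok = True
                    break
            if not ok:
                if s.zone == "PARACORTICAL":
                    return None, s
                warnings.warn(f"{ln_id}: dropping an unplaceable {s.zone} "
                              f"vessel (focus full)", stacklevel=2)
        return kept, None

    for _attempt in range(5):
        kept_idx, stuck = _place_all()
        if stuck is None:
            break
    else:
        raise GenerationError(
            f"{ln_id}: could not place a {stuck.zone}/{stuck.dilation_class} "
            f"vessel after bounded retries (tissue too crowded)")
    specs = [specs[i] for i in sorted(kept_idx)]

    # -- lymphocyte blobs ----------------------------------------------------
    blobs: List[BlobSpec] = []
    if specs:
        v_x = np.array([s.center[0] for s in specs])
        v_y = np.array([s.center[1] for s in specs])
        v_r = np.array([s.r_out for s in specs])
    else:
        v_x = v_y = v_r = np.zeros(0)

    def _clear_of_vessels(x, y, br, skip=None):
        """Blob centre must stay outside every vessel's marker ring."""
        d = np.hypot(x - v_x, y - v_y) - (v_r + 11.0 + br)
        if skip is not None:
            d[skip] = np.inf
        return bool((d >= 0).all()) if d.size else True

    def _clear_of_blobs(x, y, br, bxs, bys, brs):
        if not bxs:
            return True
        d = np.hypot(x - np.array(bxs), y - np.array(bys))
        return bool((d >= np.array(brs) + br + 1.5).all())

    for j, s in enumerate(specs):
        if s.n_ccl21_cells <= 0:
            continue
        a, bb = s.lumen_axes
        t = s.wall_thickness
        bxs: List[float] = []
        bys: List[float] = []
        brs: List[float] = []
        n_cd3 = int(round(s.cd3_fraction * s.n_ccl21_cells))
        cd3_flags = np.zeros(s.n_ccl21_cells, bool)
        cd3_flags[:n_cd3] = True
        rng.shuffle(cd3_flags)
        n_ok = 0
        for k in range(s.n_ccl21_cells):
            br = float(rng.uniform(*BLOB_RADIUS_UM))
            for _try in range(60):
                phi = rng.uniform(0, 2 * np.pi)
                r_wall = _ellipse_radius_at(a + t, bb + t, np.array([phi]))[0]
                rr = r_wall + rng.uniform(BLOB_BAND_UM[0] + br, BLOB_BAND_UM[1] - br)
                x = s.center[0] + rr * np.cos(phi + s.theta)
                y = s.center[1] + rr * np.sin(phi + s.theta)
                if np.hypot(x - cx0, y - cy0) > layout.tissue_radius_um - 10.0:
                    continue
                if not _clear_of_vessels(x, y, br, skip=j):
                    continue
                if not _clear_of_blobs(x, y, br, bxs, bys, brs):
                    continue
                blobs.append(BlobSpec(center=(float(x), float(y)), radius=br,
                                      cd3_pos=bool(cd3_flags[k]), parent_vessel=j))
                bxs.append(x)
                bys.append(y)
                brs.append(br)
                n_ok += 1
                break
        s.n_ccl21_cells = n_ok  # truth reflects what was actually rendered
        if n_ok > 0:
            s.cd3_fraction = sum(1 for bspec in blobs
                                 if bspec.parent_vessel == j and bspec.cd3_pos) / n_ok
        else:
            s.cd3_fraction = 0.0

    if layout.scattered_blob_density_per_mm2 > 0:
        area_mm2 = np.pi * (layout.tissue_radius_um / 1000.0) ** 2
        n_scatter = int(rng.poisson(layout.scattered_blob_density_per_mm2 * area_mm2))
        bxs, bys, brs = [], [], []
        for _ in range(n_scatter):
            br = float(rng.uniform(*BLOB_RADIUS_UM))
            for _try in range(40):
                rr = (layout.tissue_radius_um - 15.0) * np.sqrt(rng.random())
                aa = rng.uniform(0, 2 * np.pi)
                x, y = cx0 + rr * np.cos(aa), cy0 + rr * np.sin(aa)
                if any(np.hypot(x - f.center[0], y - f.center[1]) < f.radius + 12.0
                       for f in layout.foci):
                    continue
                if not _clear_of_vessels(x, y, br + 16.0):
                    continue
                if layout.mesh_clearance_um(x, y) < br + 1.0:
                    continue
                if not _clear_of_blobs(x, y, br, bxs, bys, brs):
                    continue
                blobs.append(BlobSpec(center=(float(x), float(y)), radius=br,
                                      cd3_pos=bool(rng.random() < 0.7)))
                bxs.append(x)
                bys.append(y)
                brs.append(br)
                break

    calib = Calibration(um_per_px=profile.um_per_px)
    image, masks, truth = render_ln_image(
        specs, layout, calib=calib, noise_sd=profile.noise_sd, rng=rng,
        blobs=blobs, ln_id=ln_id)

    tissue_area = int(masks["tissue"].sum())
    burden = 100.0 * float((_geom.fill_holes(masks["tumor"]) & masks["tissue"]).sum()) \
        / tissue_area if tissue_area else float("nan")
    ln_truth = {
        "ln_id": ln_id, "group": profile.name,
        "true_burden_pct": burden,
        "true_phenotype": layout.phenotype,
        "n_vessels": len(specs),
    }
    return LNSample(ln_id=ln_id, image=image, masks=masks, truth=truth,
                    ln_truth=ln_truth, layout=layout, specs=specs, blobs=blobs)


def cohort_rngs(seed: int, n: int) -> List[np.random.Generator]:
    """Independent per-LN generators derived from one master seed."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def iter_cohort(profile: GroupProfile, seed: int):
    """Yield LNSample objects for every LN of a profile (streaming)."""
    for i, rng in enumerate(cohort_rngs(seed, profile.lns)):
        yield generate_ln(profile, rng, ln_id=f"{profile.name}_ln{i:03d}")


def generate_cohort(profile: GroupProfile, seed: int, out_dir) -> dict:
    """Render a whole cohort to disk: images, masks, truth tables, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cmap = ChannelMap.default()
    cmap.to_yaml(out / "channel_map.yaml")
    files = []
    truths = []
    ln_truths = []
    for sample in iter_cohort(profile, seed):
        fname = f"{sample.ln_id}.tiff"
        write_multiplex(sample.image, out / fname, cmap)
        files.append({"path": fname, "ln_id": sample.ln_id, "group": profile.name})
        truths.append(sample.truth)
        ln_truths.append(sample.ln_truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    truth.to_csv(out / "truth_vessels.csv", index=False)
    pd.DataFrame(ln_truths).to_csv(out / "truth_lns.csv", index=False)
    manifest = {
        "seed": int(seed),
        "profile": profile.to_dict(),
        "profile_hash": profile.content_hash(),
        "um_per_px": profile.um_per_px,
        "channel_map": list(cmap.names),
        "images": files,
        "truth_vessels": "truth_vessels.csv",
        "truth_lns": "truth_lns.csv",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
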