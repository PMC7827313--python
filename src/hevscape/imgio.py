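"""Multichannel image, mask and table I/O with strict validation.

Images travel as multi-page TIFFs, one page per marker; channel identity is
carried by a sidecar channel map (an ordered page-index -> name list) rather
than TIFF metadata, which is unreliable in biobank exports. All validation
failures raise before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: canonical channel names, in the packaged page order
CHANNELS = ("DAPI", "PNAD", "CLDN5", "CCL21", "ASMA", "CK", "CD3", "HS")


class ValidationError(ValueError):
    """Raised when an input file, map or calibration is inconsistent."""


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size, carried unchanged through the pipeline."""

    um_per_px: float

    def __post_init__(self) -> None:
        if not (self.um_per_px > 0):
            raise ValidationError(f"um_per_px must be > 0, got {self.um_per_px}")

    def px(self, um: float) -> float:
        """Length in pixels for a length in micrometres."""
        return um / self.um_per_px

    def um2_per_px2(self) -> float:
        return self.um_per_px ** 2


@dataclass(frozen=True)
class ChannelMap:
    """Ordered page-index -> channel-name mapping (bijective over pages used)."""

    names: tuple

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dup = [n for n in self.names if list(self.names).count(n) > 1]
            raise ValidationError(f"duplicate channel name(s) in map: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls) -> "ChannelMap":
        return cls(names=CHANNELS)

    @classmethod
    def from_yaml(cls, path) -> "ChannelMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            names = data["channels"]
        else:
            names = data
        return cls(names=tuple(str(n) for n in names))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"channels": list(self.names)}, fh, sort_keys=False)


@dataclass
class MultiplexImage:
    """Named 2D intensity planes sharing one micrometre-per-pixel calibration."""

    planes: Dict[str, np.ndarray]
    calibration: Calibration

    def __post_init__(self) -> None:
        shapes = {name: p.shape for name, p in self.planes.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"planes disagree in shape: {shapes}")
        for name, p in self.planes.items():
            if p.ndim != 2:
                raise ValidationError(f"plane {name!r} is not 2D (ndim={p.ndim})")

    @property
    def shape(self) -> tuple:
        return next(iter(self.planes.values())).shape

    def __contains__(self, channel: str) -> bool:
        return channel in self.planes

    def plane(self, channel: str) -> np.ndarray:
        if channel not in self.planes:
            raise ValidationError(
                f"channel {channel!r} missing (have {sorted(self.planes)})")
        return self.planes[channel]


def to_8bit_scale(plane: np.ndarray) -> np.ndarray:
    """Linear rescale of a plane to the 0–255 scale, as float.

    uint16 data is divided by 257 (65535 -> 255); uint8/float data on a 0–255
    scale passes through unchanged.
    """
    arr = np.asarray(plane)
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 257.0
    return arr.astype(np.float32)


def read_multiplex(path, channel_map: ChannelMap, calibration: Calibration) -> MultiplexImage:
    """Read a multi-page TIFF into named planes with a calibration attached."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        n_pages = len(tf.pages)
        if n_pages < len(channel_map):
            raise ValidationError(
                f"{path.name}: channel map references page {len(channel_map) - 1} "
                f"but file has only {n_pages} page(s)")
        planes = {name: tf.pages[i].asarray() for i, name in enumerate(channel_map.names)}
    return MultiplexImage(planes=planes, calibration=calibration)


def write_multiplex(image: MultiplexImage, path, channel_map: ChannelMap | None = None) -> None:
    """Write planes as a multi-page TIFF in channel-map page order."""
    if channel_map is None:
        channel_map = ChannelMap(names=tuple(image.planes))
    for name in channel_map.names:
        if name not in image.planes:
            raise ValidationError(f"cannot write: plane {name!r} missing")
    stack = np.stack([image.planes[name] for name in channel_map.names])
    tifffile.imwrite(str(path), stack)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 single-page TIFF mask as boolean."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# tabular outputs

#: stable column order of the per-vessel table
VESSEL_COLUMNS = [
    "ln_id", "vessel_id", "centroid_x_um", "centroid_y_um", "zone",
    "diameter_um", "dilation_class", "ec_thickness_um", "thin_flag",
    "pnad_coverage", "pnad_discontinuous",
    "ccl21_coverage", "ccl21_category",
    "asma_coverage", "asma_category",
    "hs_coverage", "hs_category",
    "n_blobs", "cd3_category", "border_touching", "wall_area_um2",
]


def vessels_to_frame(records: Sequence) -> pd.DataFrame:
    """Per-vessel records (dataclasses or dicts) to a tidy DataFrame."""
    rows = []
    for r in records:
        d = r if isinstance(r, dict) else r.to_row()
        rows.append({c: d.get(c) for c in VESSEL_COLUMNS})
    return pd.DataFrame(rows, columns=VESSEL_COLUMNS)


def write_tables(records: Sequence, path) -> Path:
    """Write a per-vessel CSV with the documented stable column order.

    An empty record list produces a header-only CSV. Floats are written at
    full (repr) precision so that re-reading reproduces every numeric field.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = vessels_to_frame(records)
    frame.to_csv(path, index=False)
    return path


def write_frame(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
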