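"""Internal geometry primitives shared by the generator and the pipeline.

Binary morphology with micrometre radii is implemented through exact
Euclidean distance transforms, which is O(N) per operation and independent
of the structuring-element size (a plain disk closing at 50 px radius on a
4 Mpx plane would otherwise dominate the runtime).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def dilate_um(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    """Euclidean dilation of a boolean mask by a physical radius."""
    mask = np.asarray(mask, bool)
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask)
    return d * um_per_px <= radius_um


def erode_um(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    mask = np.asarray(mask, bool)
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(mask)
    return d * um_per_px > radius_um


def close_um(mask: np.ndarray, radius_um: float, um_per_px: float) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a physical radius."""
    mask = np.asarray(mask, bool)
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    grown = dilate_um(mask, radius_um, um_per_px)
    # erode the grown mask; pixels of the original always survive the erosion
    d = ndimage.distance_transform_edt(grown)
    return (d * um_per_px > radius_um) | mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(np.asarray(mask, bool))


def ellipse_mask(shape: tuple, center_px: tuple, a_px: float, b_px: float,
                 theta: float = 0.0) -> np.ndarray:
    """Boolean mask of a rotated filled ellipse (semi-axes in pixels).

    ``center_px`` is (x, y) in pixel coordinates; theta rotates the semi-major
    axis counter-clockwise. A non-positive semi-axis yields an empty mask.
    """
    if a_px <= 0 or b_px <= 0:
        return np.zeros(shape, bool)
    h, w = shape
    cx, cy = center_px
    x0, x1 = max(0, int(cx - a_px - 2)), min(w, int(cx + a_px + 3))
    y0, y1 = max(0, int(cy - a_px - 2)), min(h, int(cy + a_px + 3))
    out = np.zeros(shape, bool)
    if x0 >= x1 or y0 >= y1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    out[y0:y1, x0:x1] = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
    return out


def polar_angles(shape: tuple, center_px: tuple, theta: float = 0.0):
    """Angle (radians, in [0, 2pi)) of every pixel around a centre, in a frame
    rotated by *theta* (so arcs defined in a vessel's own frame line up)."""
    h, w = shape
    cx, cy = center_px
    yy, xx = np.mgrid[0:h, 0:w]
    ang = np.arctan2(yy - cy, xx - cx) - theta
    return np.mod(ang, 2 * np.pi)


def arc_mask(angles: np.ndarray, start: float, frac: float) -> np.ndarray:
    """Pixels whose angle lies inside a contiguous arc of angular fraction
    *frac* starting at *start* (radians)."""
    if frac >= 1.0:
        return np.ones_like(angles, bool)
    if frac <= 0.0:
        return np.zeros_like(angles, bool)
    rel = np.mod(angles - start, 2 * np.pi)
    return rel <= frac * 2 * np.pi


def ellipse_perimeter_um(a_um: float, b_um: float) -> float:
    """Ramanujan approximation of an ellipse perimeter."""
    if a_um <= 0 and b_um <= 0:
        return 0.0
    a, b = max(a_um, 0.0), max(b_um, 0.0)
    h = ((a - b) / (a + b)) ** 2 if (a + b) > 0 else 0.0
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
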