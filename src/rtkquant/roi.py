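"""ROI intensity measurement on single-channel images.

Membership uses the pixel-centre rule: pixel (row r, column c) belongs to a
polygon iff the point (x=c, y=r) lies inside or on the polygon boundary.
Coordinates are 0-based; ROI intensities are integrated (summed) pixel values,
so the whole-cell minus interior subtraction isolates the membrane ring.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry import Polygon

from .exceptions import GeometryError, ValidationError

__all__ = ["polygon_pixel_mask", "measure_roi_intensity", "membrane_intensity"]


def polygon_pixel_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside ``polygon``.

    Parameters
    ----------
    shape : (n_rows, n_cols)
    polygon : shapely Polygon or (n, 2) array of (x, y) vertices
    """
    if not isinstance(polygon, Polygon):
        polygon = Polygon(np.asarray(polygon, dtype=float))
    if not polygon.is_valid:
        raise GeometryError("polygon is not a simple (non-self-intersecting) ring")
    minx, miny, maxx, maxy = polygon.bounds
    nrows, ncols = shape
    if minx < -0.5 or miny < -0.5 or maxx > ncols - 0.5 or maxy > nrows - 0.5:
        raise GeometryError(
            f"polygon bounds {polygon.bounds} extend outside image shape {shape}"
        )
    c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, ncols)
    r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, nrows)
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    # intersects_xy == containment including the boundary, at pixel centres
    shapely.prepare(polygon)
    inside = shapely.intersects_xy(polygon, cc.ravel(), rr.ravel())
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def measure_roi_intensity(
    image: np.ndarray, roi, background_per_pixel: float = 0.0
) -> float:
    """Integrated background-corrected intensity inside an ROI polygon.

    Returns ``sum(pixels in roi) - background_per_pixel * n_pixels``. The
    background is the mean per-pixel intensity of untransfected-cell (or
    cell-free) regions, scaled by the ROI area so the correction is robust to
    ROI size.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("image must be a 2-D single-channel array")
    if background_per_pixel < 0:
        raise ValidationError("background_per_pixel must be >= 0")
    mask = polygon_pixel_mask(image.shape, roi)
    n = int(mask.sum())
    if n == 0:
        raise GeometryError("ROI contains no pixel centres")
    return float(image[mask].sum() - background_per_pixel * n)


def membrane_intensity(i_roi1: float, i_roi2: float) -> float:
    """Membrane intensity I_m = I_roi1 - I_roi2 (exact subtraction).

    Whole-cell intensity minus interior intensity leaves the peripheral
    (plasma-membrane) signal. A negative result is returned with a warning;
    it indicates a noise-dominated cell, which callers flag rather than drop.
    """
    if not (np.isfinite(i_roi1) and np.isfinite(i_roi2)):
        raise ValidationError("ROI intensities must be finite")
    i_m = float(i_roi1) - float(i_roi2)
    if i_m < 0:
        warnings.warn(
            f"negative membrane intensity ({i_m:.3g}): noise-dominated cell",
            stacklevel=2,
        )
    return i_m
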