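"""Raw RGB-D capture -> calibrated height map.

A capture is a stack of depth frames (10 in the reference rig) plus an RGB
image. The stack is averaged per pixel to suppress sensor noise, the plate
circle is located from the RGB image, the bare-plate surface depth is
estimated as the modal depth inside the plate (excluding food if a mask is
supplied), and heights above the plate plane follow from the linear depth
calibration. The plate plane is treated as orthographic: one pixel covers a
constant area.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DetectionError
from .synthetic import PlateGeometry


@dataclass
class HeightMap:
    """Heights (mm) above the plate surface on the plate interior.

    Invalid pixels (outside the plate, or with any non-finite depth reading)
    are NaN in `heights` and False in `valid_mask` — never silently zeroed.
    Depth readings below the plate plane are physically meaningless and are
    clamped to 0; `n_clamped` counts them for diagnostics.
    """

    heights: np.ndarray  # (H, W) float
    valid_mask: np.ndarray  # (H, W) bool
    n_clamped: int = 0


def average_depth_frames(stack) -> tuple:
    """Per-pixel arithmetic mean of an (n, H, W) depth-frame stack.

    Returns (mean_map, valid) where pixels with any non-finite reading are
    NaN in the map and False in `valid`.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need a non-empty (n, H, W) frame stack")
    valid = np.isfinite(stack).all(axis=0)
    mean = stack.mean(axis=0)
    mean[~valid] = np.nan
    return mean, valid


def detect_plate(rgb, min_area_frac=0.02) -> tuple:
    """Locate the plate circle in an overhead RGB image.

    The plate is the large bright region on a darker background; food items
    sit on it as darker holes which are filled before measuring. Returns
    (center_row, center_col, radius) in pixels.
    """
    from skimage.filters import threshold_otsu

    gray = np.asarray(rgb, dtype=float).mean(axis=-1)
    if gray.max() - gray.min() < 1.0:
        raise DetectionError("image has no contrast; no plate found")
    bright = gray > threshold_otsu(gray)
    labels, n = ndimage.label(bright)
    if n == 0:
        raise DetectionError("no bright region found")
    sizes = ndimage.sum_labels(np.ones_like(gray), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    disk = ndimage.binary_fill_holes(labels == best)
    area = float(disk.sum())
    if area < min_area_frac * gray.size:
        raise DetectionError("largest bright region is too small to be a plate")
    radius = np.sqrt(area / np.pi)
    # circularity: a disk's bounding box is ~2r x 2r
    ys, xs = np.nonzero(disk)
    extent = max(np.ptp(ys), np.ptp(xs)) + 1
    if extent > 2.4 * radius:
        raise DetectionError("largest bright region is not circular")
    return float(ys.mean()), float(xs.mean()), float(radius)


def estimate_plate_surface_depth(depth_map, geometry: PlateGeometry,
                                 food_mask=None, bin_width=1.0) -> float:
    """Modal depth of bare-plate pixels inside the plate circle.

    The mode is located on a histogram of `bin_width` depth units, then
    refined as the mean of readings within +-1.5 bins of the modal bin, which
    recovers sub-bin accuracy under symmetric sensor noise.
    """
    sel = geometry.plate_mask() & np.isfinite(depth_map)
    if food_mask is not None:
        sel &= ~food_mask
    vals = depth_map[sel]
    if vals.size == 0:
        raise ValueError("no bare-plate pixels to estimate the surface from")
    lo, hi = vals.min(), vals.max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        return float(vals.mean())
    hist, edges = np.histogram(vals, bins=edges)
    mode_center = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    near = vals[np.abs(vals - mode_center) <= 1.5 * bin_width]
    return float(near.mean())


def to_height_map(depth_map, geometry: PlateGeometry) -> HeightMap:
    """Calibrate an averaged depth map to heights (mm) above the plate.

    height = (plate_surface_depth - depth) * depth_scale; negative heights
    inside the plate are clamped to 0 and counted.
    """
    if geometry.plate_surface_depth is None:
        raise ValueError("geometry.plate_surface_depth is not calibrated")
    depth_map = np.asarray(depth_map, dtype=np.float64)
    valid = geometry.plate_mask() & np.isfinite(depth_map)
    heights = (geometry.plate_surface_depth - depth_map) * geometry.depth_scale
    negative = valid & (heights < 0)
    n_clamped = int(negative.sum())
    heights[negative] = 0.0
    heights[~valid] = np.nan
    return HeightMap(heights=heights, valid_mask=valid, n_clamped=n_clamped)


def calibrated_height_map(scene, surface_depth=None) -> HeightMap:
    """Average a scene's depth stack and calibrate it to heights.

    `surface_depth` overrides the scene geometry's plate surface depth (the
    reference-plate estimate is normally reused across a meal's plates).
    """
    mean, _ = average_depth_frames(scene.depth_stack)
    geom = scene.geometry
    if surface_depth is not None:
        geom = dataclasses.replace(geom, plate_surface_depth=float(surface_depth))
    return to_height_map(mean, geom)
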