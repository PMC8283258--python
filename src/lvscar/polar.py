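"""Polar re-encoding of anatomical masks about the blood-pool centroid.

The network input is a 256x256 polar raster: rows index radius at 1 mm per
step starting at 0 mm, columns index angle at 360/256 degrees per step,
measured counter-clockwise from the +x direction of the mask frame.  The
origin of the transform is the centroid of the blood pool (the background
region fully enclosed by the myocardial wall).  Radial rows beyond the
sampled extent are zero-padded back to 256.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import GRID_SIZE, RESOLUTION_MM, AnatomicalMask

__all__ = ["PolarMask", "blood_pool_centroid", "to_polar", "pad_polar"]

ANGULAR_STEPS = GRID_SIZE  # 360/256 degrees per column


@dataclass
class PolarMask:
    """256x256 binary polar raster; rows = radius (mm), columns = angle."""

    grid: np.ndarray
    radial_resolution: float = RESOLUTION_MM
    angular_resolution: float = 360.0 / ANGULAR_STEPS
    center_used: np.ndarray = field(default_factory=lambda: np.zeros(2))
    patient_id: str = ""
    slice_index: int = 0
    normalized_position: float = 0.0
    label: int = 0


def blood_pool_centroid(mask: AnatomicalMask) -> np.ndarray:
    """Centroid (mm) of the cavity: background fully enclosed by foreground.

    Background connected components touching the raster border are outside
    the heart; everything else is blood pool.  Apical cap discs have no
    cavity and fall back to the foreground centroid with a warning.
    """
    grid = mask.grid
    if grid.sum() == 0:
        raise ValueError("empty mask has no centroid")
    labeled, n = ndimage.label(grid == 0)
    border = np.unique(
        np.concatenate([labeled[0, :], labeled[-1, :], labeled[:, 0], labeled[:, -1]])
    )
    enclosed = np.isin(labeled, border, invert=True) & (labeled > 0)
    if enclosed.any():
        rows, cols = np.nonzero(enclosed)
    else:
        warnings.warn(
            "mask has no enclosed cavity; using foreground centroid", stacklevel=2
        )
        rows, cols = np.nonzero(grid)
    return mask.origin + np.array([cols.mean(), rows.mean()]) * mask.resolution


def to_polar(
    mask: AnatomicalMask,
    center: np.ndarray | None = None,
    size: int = GRID_SIZE,
) -> PolarMask:
    """Nearest-neighbour polar resampling of a Cartesian mask about ``center``.

    Output pixel ``(r, c)`` samples the input at
    ``center + r * radial_resolution * (cos th, sin th)`` with
    ``th = c * angular_resolution``; samples outside the input grid are zero.
    The result is zero-padded at the large-radius end to ``size`` rows.
    """
    if center is None:
        center = blood_pool_centroid(mask)
    center = np.asarray(center, dtype=float)
    grid = mask.grid
    h, w = grid.shape
    lo = mask.origin - 0.5 * mask.resolution
    hi = mask.origin + (np.array([w, h]) - 0.5) * mask.resolution
    if not (lo[0] <= center[0] <= hi[0] and lo[1] <= center[1] <= hi[1]):
        raise ValueError(f"polar center {center} lies outside the mask grid")

    # largest radius that can still hit the grid from this center
    corners = np.array([[lo[0], lo[1]], [lo[0], hi[1]], [hi[0], lo[1]], [hi[0], hi[1]]])
    r_max = float(np.linalg.norm(corners - center, axis=1).max())
    n_rows = min(size, int(np.ceil(r_max / RESOLUTION_MM)) + 1)

    r = np.arange(n_rows) * RESOLUTION_MM
    theta = np.arange(ANGULAR_STEPS) * (2.0 * np.pi / ANGULAR_STEPS)
    xs = center[0] + r[:, None] * np.cos(theta)[None, :]
    ys = center[1] + r[:, None] * np.sin(theta)[None, :]
    cols = np.rint((xs - mask.origin[0]) / mask.resolution).astype(np.int64)
    rows = np.rint((ys - mask.origin[1]) / mask.resolution).astype(np.int64)
    valid = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    out = np.zeros((n_rows, ANGULAR_STEPS), dtype=np.uint8)
    out[valid] = grid[rows[valid], cols[valid]]

    polar = PolarMask(
        grid=out,
        center_used=center,
        patient_id=mask.patient_id,
        slice_index=mask.slice_index,
        normalized_position=mask.normalized_position,
    )
    return pad_polar(polar, size=size)


def pad_polar(mask: PolarMask, size: int = GRID_SIZE) -> PolarMask:
    """Zero-pad rows at the large-radius end to exactly ``size`` x 256."""
    grid = mask.grid
    if grid.shape[0] > size:
        raise ValueError(f"polar mask has {grid.shape[0]} rows, more than {size}")
    if grid.shape[0] == size:
        return mask
    pad = np.zeros((size - grid.shape[0], grid.shape[1]), dtype=grid.dtype)
    mask.grid = np.vstack([grid, pad])
    return mask
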