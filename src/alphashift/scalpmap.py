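"""Scalp topography: interpolation of channel values onto a regular grid.

Per-channel statistics are linearly interpolated (piecewise-linear on
the Delaunay triangulation of the electrode positions) onto a 32 x 32
node grid spanning the bounding square of the head circle, then
smoothed with an isotropic Gaussian kernel (sigma = 8 mm by default).
Nodes outside the convex hull of the electrodes are masked, never
extrapolated; smoothing is mask-normalized so constants are preserved
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import QhullError

from .montage import MontageLayout

GRID_N = 32
DEFAULT_SIGMA_MM = 8.0


@dataclass
class ScalpMap:
    """Values on a regular 2-D grid over the scalp with a validity mask."""

    grid: np.ndarray  # (GRID_N, GRID_N); entries outside mask are NaN
    x: np.ndarray  # node x coordinates (mm), ascending
    y: np.ndarray  # node y coordinates (mm), ascending
    mask: np.ndarray  # bool, True = inside interpolation support
    smoothing_sigma: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise ValueError("grid and mask shapes differ")
        if self.grid.shape != (len(self.y), len(self.x)):
            raise ValueError("grid shape must be (len(y), len(x))")
        dx, dy = np.diff(self.x), np.diff(self.y)
        if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0])):
            raise ValueError("grid spacing must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def values(self) -> np.ndarray:
        """Unmasked node values as a flat vector (row-major order)."""
        return self.grid[self.mask]

    def node_xy(self) -> np.ndarray:
        """Coordinates of the unmasked nodes, matching ``values()``."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx[self.mask], yy[self.mask]])

    def with_values(self, values: np.ndarray) -> "ScalpMap":
        """A copy with the unmasked nodes replaced by ``values``."""
        grid = np.full_like(self.grid, np.nan)
        grid[self.mask] = values
        return ScalpMap(grid=grid, x=self.x, y=self.y, mask=self.mask.copy(),
                        smoothing_sigma=self.smoothing_sigma)


def interpolate_map(values, layout: MontageLayout,
                    grid_n: int = GRID_N) -> ScalpMap:
    """Piecewise-linear interpolation of per-channel values onto the grid.

    The grid spans the bounding square of the head circle; nodes outside
    the convex hull of the electrodes are masked (NaN).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(layout.labels),):
        raise ValueError("one value per layout channel required")
    if not np.isfinite(values).all():
        raise ValueError("channel values must be finite")
    R = layout.head_radius
    x = np.linspace(-R, R, grid_n)
    y = np.linspace(-R, R, grid_n)
    xx, yy = np.meshgrid(x, y)
    try:
        interp = LinearNDInterpolator(layout.xy, values)
    except QhullError as err:
        raise ValueError("need >= 3 non-collinear electrodes") from err
    grid = interp(xx, yy)
    return ScalpMap(grid=grid, x=x, y=y, mask=np.isfinite(grid))


def smooth_map(m: ScalpMap, sigma_mm: float = DEFAULT_SIGMA_MM) -> ScalpMap:
    """Mask-normalized Gaussian smoothing.

    Convolution is restricted to the mask and renormalized by the
    smoothed mask, so constant maps are unchanged at boundaries;
    sigma = 0 is the identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return ScalpMap(grid=m.grid.copy(), x=m.x, y=m.y,
                        mask=m.mask.copy(), smoothing_sigma=0.0)
    sigma_px = sigma_mm / m.spacing
    filled = np.where(m.mask, m.grid, 0.0)
    num = gaussian_filter(filled, sigma_px, mode="constant")
    den = gaussian_filter(m.mask.astype(float), sigma_px, mode="constant")
    grid = np.full_like(m.grid, np.nan)
    grid[m.mask] = num[m.mask] / den[m.mask]
    return ScalpMap(grid=grid, x=m.x, y=m.y, mask=m.mask.copy(),
                    smoothing_sigma=sigma_mm)


def subject_maps_matrix(maps: list[ScalpMap]) -> np.ndarray:
    """Stack per-subject maps into a (subjects, unmasked-nodes) matrix."""
    if not maps:
        raise ValueError("no maps")
    ref = maps[0].mask
    for m in maps[1:]:
        if m.grid.shape != ref.shape or not np.array_equal(m.mask, ref):
            raise ValueError("all maps must share grid and mask")
    return np.stack([m.values() for m in maps])
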