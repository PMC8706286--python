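"""Pattern-recognition representations of a two-condition fingerprint.

The potential axis is deliberately discarded: each grid potential
contributes one point (x, y) = (normalized current under water/PBS,
normalized current under ethanol/ABS).  The resulting point cloud on
[0, 1]² is summarized three ways — the raw scatter, a kernel density
map whose dense regions highlight where the two conditions respond
together, and a binned heatmap whose count of "hot areas" (connected
high-count regions) serves as a compact species-discriminating feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SpeciesFingerprint
from .errors import DegenerateInputError, InvalidArgumentError

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class FusedPointSet:
    """Potential-free point cloud; one (x, y) pair per grid potential."""

    species_id: str
    points: np.ndarray  # (N, 2) in [0, 1]^2

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidArgumentError("points must be an (N, 2) array")


@dataclass
class DensityMap:
    """Product-Gaussian KDE evaluated at the cell centers of a G×G grid.

    Values are renormalized so that sum(value) × cell_area == 1.
    """

    species_id: str
    values: np.ndarray  # (G, G); [i, j] = cell (x_i, y_j)
    bandwidth: tuple[float, float]
    grid_size: int


@dataclass
class Heatmap:
    """B×B histogram of the fused points over [0, 1]²."""

    species_id: str
    counts: np.ndarray  # (B, B) int; [i, j] = cell (x_i, y_j)
    bins: int


def fuse_conditions(fingerprint: SpeciesFingerprint) -> FusedPointSet:
    """Pair the two condition traces pointwise, deleting the potential."""
    try:
        x = np.asarray(fingerprint.traces["water_PBS"], dtype=float)
        y = np.asarray(fingerprint.traces["ethanol_ABS"], dtype=float)
    except KeyError as exc:
        raise InvalidArgumentError(f"fingerprint missing condition {exc}") from None
    if len(x) != len(y):
        raise InvalidArgumentError("condition traces must share the canonical grid")
    return FusedPointSet(fingerprint.species_id, np.column_stack([x, y]))


def _check_unit_square(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if np.any(pts < -1e-12) or np.any(pts > 1 + 1e-12):
        raise InvalidArgumentError("points must lie in [0, 1]^2")
    return np.clip(pts, 0.0, 1.0)


def density_map(
    points: FusedPointSet,
    grid_size: int = 50,
    bandwidth: float | tuple[float, float] | str = "scott",
) -> DensityMap:
    """Gaussian product-kernel density estimate on a G×G cell-center grid.

    Per-axis bandwidths follow Scott's rule h_j = σ_j · n^(−1/6) unless a
    numeric override is given.  The discrete density is renormalized to
    integrate to exactly 1 over the grid, so the normalization is testable
    to machine precision.
    """
    pts = _check_unit_square(points.points)
    n = len(pts)
    if n < 2 or np.all(pts == pts[0]):
        raise DegenerateInputError("need at least 2 distinct points for a density map")
    if grid_size < 2:
        raise InvalidArgumentError("grid_size must be at least 2")
    if isinstance(bandwidth, str):
        if bandwidth != "scott":
            raise InvalidArgumentError(f"unknown bandwidth rule {bandwidth!r}")
        h = pts.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
    if np.any(h <= 0):
        raise DegenerateInputError("zero bandwidth (points constant along an axis)")

    centers = (np.arange(grid_size) + 0.5) / grid_size
    # (G, n) kernel matrices per axis; the product kernel factorizes.
    kx = np.exp(-0.5 * ((centers[:, None] - pts[None, :, 0]) / h[0]) ** 2)
    ky = np.exp(-0.5 * ((centers[:, None] - pts[None, :, 1]) / h[1]) ** 2)
    values = kx @ ky.T / (n * 2.0 * np.pi * h[0] * h[1])
    cell_area = 1.0 / grid_size**2
    values /= values.sum() * cell_area
    return DensityMap(points.species_id, values, (float(h[0]), float(h[1])), grid_size)


def heatmap(points: FusedPointSet, bins: int = 25) -> Heatmap:
    """2D histogram over [0, 1]² with B×B equal cells.

    The last cell along each axis is closed on the right/top, so boundary
    points at coordinate 1.0 are counted.
    """
    if bins < 2:
        raise InvalidArgumentError("bins must be at least 2")
    pts = _check_unit_square(points.points)
    counts, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    return Heatmap(points.species_id, counts.astype(int), bins)


def _map_values(source: Heatmap | DensityMap | np.ndarray) -> np.ndarray:
    if isinstance(source, Heatmap):
        return source.counts
    if isinstance(source, DensityMap):
        return source.values
    return np.asarray(source, dtype=float)


def hot_area_labels(
    source: Heatmap | DensityMap | np.ndarray, threshold_quantile: float = 0.75
) -> np.ndarray:
    """Label 8-connected components of cells strictly above threshold.

    The threshold is the given quantile of the *nonzero* cell values.
    Returns an int array of the map's shape (0 = not hot, 1..k = area id).
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise InvalidArgumentError("threshold_quantile must lie in (0, 1)")
    values = _map_values(source)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return np.zeros(values.shape, dtype=int)
    threshold = np.quantile(nonzero, threshold_quantile)
    labeled, _ = ndimage.label(values > threshold, structure=_EIGHT_CONNECTED)
    return labeled


def count_hot_areas(
    source: Heatmap | DensityMap | np.ndarray, threshold_quantile: float = 0.75
) -> int:
    """Number of 8-connected hot areas (0 for an all-zero map)."""
    return int(hot_area_labels(source, threshold_quantile).max())
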