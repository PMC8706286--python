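"""Feature-matrix construction and principal component analysis.

Every species' two normalized condition traces are concatenated into one
feature vector (2 × grid length columns), giving a taxa × features
matrix on a common [0, 1] scale.  PCA is computed by singular value
decomposition of the column-centered matrix — equivalent to the
eigendecomposition of the sample covariance — with a deterministic sign
convention so results are identical across runs and platforms.

Columns are intentionally *not* standardized by default: the traces
already share a scale, and standardizing hundreds of correlated columns
would inflate noise in flat regions of the voltammograms.  Correlation-
matrix PCA is available via ``standardize=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CONDITIONS, SpeciesFingerprint
from .errors import DegenerateInputError, InvalidArgumentError


def build_feature_matrix(
    fingerprints: Sequence[SpeciesFingerprint],
    mode: str = "concatenate",
) -> pd.DataFrame:
    """Assemble the taxa × features matrix.

    ``mode="concatenate"`` (default) lays the water/PBS trace before the
    ethanol/ABS trace, labeling columns by (condition, potential).
    ``mode="sum"`` instead overlays the two traces pointwise and rescales
    the sum back onto [0, 1] (half the columns).
    """
    if not fingerprints:
        raise InvalidArgumentError("no fingerprints supplied")
    grid = fingerprints[0].grid
    for fp in fingerprints:
        if fp.grid != grid:
            raise InvalidArgumentError(
                f"fingerprint for {fp.species_id!r} is not on the shared grid"
            )
    potentials = np.round(grid.potentials, 4)
    rows = []
    for fp in fingerprints:
        traces = [np.asarray(fp.traces[c], dtype=float) for c in CONDITIONS]
        if mode == "concatenate":
            rows.append(np.concatenate(traces))
        elif mode == "sum":
            total = traces[0] + traces[1]
            span = total.max() - total.min()
            if span == 0:
                raise DegenerateInputError(
                    f"summed trace for {fp.species_id!r} is constant"
                )
            rows.append((total - total.min()) / span)
        else:
            raise InvalidArgumentError(f"unknown feature mode {mode!r}")
    if mode == "concatenate":
        columns = pd.MultiIndex.from_tuples(
            [(c, p) for c in CONDITIONS for p in potentials],
            names=["condition", "potential_V"],
        )
    else:
        columns = pd.MultiIndex.from_tuples(
            [("overlay", p) for p in potentials], names=["condition", "potential_V"]
        )
    return pd.DataFrame(rows, index=[fp.species_id for fp in fingerprints], columns=columns)


@dataclass
class PCAResult:
    """Loadings (components × features), scores (taxa × components) and
    explained-variance ratios, plus the column means used for centering."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def pca(X: pd.DataFrame | np.ndarray, n_components: int, standardize: bool = False) -> PCAResult:
    """PCA via SVD of the centered data matrix.

    Explained-variance ratios are eigenvalues of the sample covariance
    divided by total variance.  Each component's sign is fixed so its
    largest-magnitude loading entry is positive.
    """
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise InvalidArgumentError("X must be 2-D with at least 2 rows")
    n, p = A.shape
    max_components = min(n - 1, p)
    if not 1 <= n_components <= max_components:
        raise InvalidArgumentError(
            f"n_components must lie in [1, {max_components}] for a {n}x{p} matrix"
        )
    mean = A.mean(axis=0)
    centered = A - mean
    if standardize:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError("constant column cannot be standardized")
        centered = centered / sd
    total_variance = float((centered**2).sum()) / (n - 1)
    if total_variance == 0.0:
        raise DegenerateInputError("zero total variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    ratios = (s**2 / (n - 1)) / total_variance
    loadings = vt[:n_components].copy()
    scores = (u[:, :n_components] * s[:n_components]).copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(loadings, scores, ratios[:n_components].copy(), mean)
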