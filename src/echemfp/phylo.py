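"""Distance-based clustering of fingerprints into a phenetic dendrogram.

The dendrogram is built by agglomerative clustering — UPGMA (average
linkage) by default — on pairwise distances between fingerprint feature
vectors.  Merge heights are half the inter-cluster distance, so the tree
is ultrametric and exports cleanly to Newick.  Deterministic min-index
tie-breaking makes output identical across platforms.

Evaluation helpers quantify what a figure would only show: cophenetic
correlation (how faithfully the dendrogram encodes the input distances)
and the adjusted Rand index against known partitions (e.g. planted
clades or the ingroup/outgroup split of a synthetic world).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .errors import DegenerateInputError, InvalidArgumentError

_METRICS = ("euclidean", "correlation")
_LINKAGES = ("average", "single", "complete")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities between labeled taxa."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidArgumentError("matrix shape must match the number of ids")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("distances must be finite")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise InvalidArgumentError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InvalidArgumentError("diagonal must be zero")
        if np.any(self.values < 0):
            raise InvalidArgumentError("distances must be non-negative")


class Merge(NamedTuple):
    """One agglomeration step: clusters ``a`` and ``b`` join at ``height``.

    Cluster ids follow the usual convention: leaves are 0..n−1, the
    cluster created by merge ``i`` has id ``n + i``.
    """

    a: int
    b: int
    height: float
    size: int


@dataclass
class Dendrogram:
    """Ordered merge list over labeled leaves (n − 1 merges for n leaves)."""

    labels: list[str]
    merges: list[Merge]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (third column = merge *distance*,
        i.e. twice the merge height)."""
        return np.array(
            [[m.a, m.b, 2.0 * m.height, m.size] for m in self.merges], dtype=float
        )

    def cluster_members(self) -> list[set[int]]:
        """Member leaf indices for every cluster id 0..2n−2."""
        members: list[set[int]] = [{i} for i in range(self.n_leaves)]
        for m in self.merges:
            members.append(members[m.a] | members[m.b])
        return members


def distance_matrix(
    X: pd.DataFrame | np.ndarray,
    metric: str = "euclidean",
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distances between feature rows.

    ``euclidean`` is plain L2; ``correlation`` is 1 − Pearson correlation
    (constant rows are rejected since their correlation is undefined).
    """
    if metric not in _METRICS:
        raise InvalidArgumentError(f"metric must be one of {_METRICS}")
    if isinstance(X, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in X.index]
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(A.shape[0])]
    if A.ndim != 2 or A.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 feature rows")
    if metric == "correlation" and np.any(A.std(axis=1) == 0):
        raise DegenerateInputError("constant row has no defined correlation distance")
    D = squareform(pdist(A, metric=metric))
    # pdist can leave tiny negative round-off in correlation distances
    np.clip(D, 0.0, None, out=D)
    return DistanceMatrix(list(ids), D)


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration; see :func:`agglomerate`."""
    return agglomerate(D, linkage="average")


def agglomerate(D: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    At each step the pair of active clusters at minimal inter-cluster
    distance merges at height distance/2; ties resolve to the smallest
    (first index, then second index) pair.  For ``average`` linkage the
    distance from the merged cluster to any other is the size-weighted
    mean (Lance–Williams), i.e. the unweighted average over leaf pairs —
    UPGMA proper.  ``single`` and ``complete`` use min and max.
    """
    if linkage not in _LINKAGES:
        raise InvalidArgumentError(f"linkage must be one of {_LINKAGES}")
    n = len(D.ids)
    if n < 2:
        raise InvalidArgumentError("need at least 2 taxa")
    m = 2 * n - 1
    # S holds true inter-cluster distances; A is the argmin view with the
    # lower triangle and inactive rows/columns masked to +inf, so a flat
    # row-major argmin realizes the (min i, then min j) tie-break.
    S = np.full((m, m), np.inf)
    S[:n, :n] = D.values
    A = np.full((m, m), np.inf)
    iu = np.triu_indices(n, k=1)
    A[iu] = D.values[iu]
    sizes = np.zeros(m, dtype=int)
    sizes[:n] = 1
    active = np.zeros(m, dtype=bool)
    active[:n] = True

    merges: list[Merge] = []
    for step in range(n - 1):
        flat = int(np.argmin(A))
        i, j = divmod(flat, m)
        d = A[i, j]
        new = n + step
        merges.append(Merge(i, j, d / 2.0, sizes[i] + sizes[j]))
        active[i] = active[j] = False
        A[i, :] = A[:, i] = np.inf
        A[j, :] = A[:, j] = np.inf
        others = np.flatnonzero(active)
        if others.size:
            if linkage == "average":
                d_new = (sizes[i] * S[i, others] + sizes[j] * S[j, others]) / (
                    sizes[i] + sizes[j]
                )
            elif linkage == "single":
                d_new = np.minimum(S[i, others], S[j, others])
            else:
                d_new = np.maximum(S[i, others], S[j, others])
            S[new, others] = S[others, new] = d_new
            A[others, new] = d_new  # others < new, upper triangle
        sizes[new] = sizes[i] + sizes[j]
        active[new] = True
    return Dendrogram(list(D.ids), merges)


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into ``k`` clusters by undoing the last k−1 merges.

    Labels are 1..k, ordered by each cluster's first-appearing taxon.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise InvalidArgumentError(f"k must lie in [1, {n}]")
    members = dendrogram.cluster_members()
    roots = set(range(n))
    for step, m in enumerate(dendrogram.merges[: n - k]):
        roots.discard(m.a)
        roots.discard(m.b)
        roots.add(n + step)
    ordered = sorted(roots, key=lambda c: min(members[c]))
    labels: dict[str, int] = {}
    for rank, cluster in enumerate(ordered, start=1):
        for leaf in members[cluster]:
            labels[dendrogram.labels[leaf]] = rank
    return labels


def to_newick(dendrogram: Dendrogram, fmt: str = "%.10g") -> str:
    """Rooted Newick string; branch length = parent height − child height.

    Leaves sit at height 0, so root-to-tip path lengths all equal the root
    height (the dendrogram is ultrametric by construction).
    """
    n = dendrogram.n_leaves
    reprs: list[str] = list(dendrogram.labels)
    heights: list[float] = [0.0] * n
    for m in dendrogram.merges:
        la = fmt % (m.height - heights[m.a])
        lb = fmt % (m.height - heights[m.b])
        reprs.append(f"({reprs[m.a]}:{la},{reprs[m.b]}:{lb})")
        heights.append(m.height)
    return reprs[-1] + ";"


def cophenetic_matrix(dendrogram: Dendrogram) -> np.ndarray:
    """Pairwise cophenetic distances: 2 × height of the lowest common cluster."""
    n = dendrogram.n_leaves
    C = np.zeros((n, n))
    members = [{i} for i in range(n)]
    for m in dendrogram.merges:
        left, right = members[m.a], members[m.b]
        for i in left:
            for j in right:
                C[i, j] = C[j, i] = 2.0 * m.height
        members.append(left | right)
    return C


def cophenetic_correlation(dendrogram: Dendrogram, D: DistanceMatrix) -> float:
    """Pearson correlation between input and cophenetic distances."""
    if dendrogram.labels != D.ids:
        raise InvalidArgumentError("dendrogram and distance matrix taxa differ")
    iu = np.triu_indices(len(D.ids), k=1)
    original = D.values[iu]
    cophenetic = cophenetic_matrix(dendrogram)[iu]
    if original.std() == 0 or cophenetic.std() == 0:
        raise DegenerateInputError("distances are constant; correlation undefined")
    return float(np.corrcoef(original, cophenetic)[0, 1])


def _align_labels(
    labels_a: Mapping[str, int], labels_b: Mapping[str, int]
) -> tuple[list[int], list[int]]:
    if set(labels_a) != set(labels_b):
        raise InvalidArgumentError("partitions must cover the same taxa")
    keys = sorted(labels_a)
    return [labels_a[k] for k in keys], [labels_b[k] for k in keys]


def adjusted_rand(labels_a: Mapping[str, int], labels_b: Mapping[str, int]) -> float:
    """Chance-corrected partition agreement (1 = identical, ≈0 = random)."""
    a, b = _align_labels(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def silhouette_report(D: DistanceMatrix, dendrogram: Dendrogram, ks: Sequence[int]) -> pd.DataFrame:
    """Mean silhouette width of the dendrogram cut at each k (advisory only)."""
    rows = []
    for k in ks:
        if not 2 <= k <= len(D.ids) - 1:
            continue
        labels = cut_clusters(dendrogram, k)
        y = [labels[i] for i in D.ids]
        rows.append({"k": k, "silhouette": float(silhouette_score(D.values, y, metric="precomputed"))})
    return pd.DataFrame(rows)


def groups_form_exclusive_clades(
    dendrogram: Dendrogram, groups: Mapping[str, Sequence[str]]
) -> list[str]:
    """Which groups do NOT appear as an exact cluster of the dendrogram.

    A group forms an exclusive clade iff its members merge with each other
    before any of them merges with an outside item — equivalently, some
    cluster's member set equals the group exactly.  Returns the ids of
    violating groups (empty list = all groups coherent).
    """
    index = {label: i for i, label in enumerate(dendrogram.labels)}
    member_sets = {frozenset(s) for s in dendrogram.cluster_members()}
    violations = []
    for gid, labels in groups.items():
        target = frozenset(index[l] for l in labels)
        if target not in member_sets:
            violations.append(gid)
    return violations
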