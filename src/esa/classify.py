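"""Distance matrices, hierarchical clustering and Rand-index scoring.

Structure classification here is purely distance-based: all pairwise
geodesic shape distances are computed, the matrix is clustered
agglomeratively with average linkage (UPGMA) and the tree is cut at a
requested number of clusters.  Agreement with reference class labels is
scored by the Rand index over all unordered pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .curves import BackboneCurve
from .matching import DEFAULT_GRID_SIZE, geodesic_distance

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(d < -1e-12):
            raise ValueError("distances must be nonnegative")
        if np.max(np.abs(d - d.T)) > 1e-8:
            raise ValueError("matrix not symmetric; symmetrize first")
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclasses.dataclass(frozen=True)
class PartitionScore:
    """Pair-counting agreement between a clustering and reference classes.

    TP: pairs together in both; TN: apart in both; FP: together in the
    prediction only; FN: together in the reference only.
    RI = (TP + TN) / (TP + TN + FP + FN).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def rand_index(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 1.0


def pairwise_distances(
    curves: Sequence[BackboneCurve],
    grid_size: int = DEFAULT_GRID_SIZE,
    symmetric: bool = True,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise geodesic shape distances, symmetrized by averaging.

    Each pair is independent, so evaluation order cannot change the result.
    A pair that fails to align is recorded as NaN and reported; by default
    this aborts (strict mode) rather than silently imputing.
    """
    curves = list(curves)
    n = len(curves)
    if n < 2:
        raise ValueError("need at least 2 curves")
    if labels is None:
        labels = [c.label or f"curve{i}" for i, c in enumerate(curves)]
    d = np.zeros((n, n))
    failed = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            d[i, j] = d[j, i] = geodesic_distance(
                curves[i], curves[j], grid_size=grid_size, symmetric=symmetric
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("distance (%d, %d) failed: %s", i, j, exc)
            d[i, j] = d[j, i] = np.nan
            failed.append((i, j))
    if failed:
        raise RuntimeError(f"{len(failed)} pair(s) failed to align: {failed}")
    return DistanceMatrix(labels=tuple(labels), values=d)


def cluster(dmat: DistanceMatrix | np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage (UPGMA) hierarchical clustering cut at n_clusters.

    Returns integer labels 1..n_clusters.  Deterministic for a given
    matrix; linkage ties are resolved by the smallest-index convention of
    the underlying implementation.
    """
    d = dmat.values if isinstance(dmat, DistanceMatrix) else np.asarray(dmat, float)
    n = d.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    # squareform requires an exactly-symmetric, zero-diagonal matrix
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=n_clusters, criterion="maxclust")


def rand_index(pred: Sequence, truth: Sequence) -> PartitionScore:
    """Rand index of a predicted partition against reference classes.

    Counts all n(n-1)/2 unordered pairs via the contingency table; the
    score is invariant to relabeling of either partition and symmetric in
    its arguments.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1D of equal length")
    n = pred.size
    if n < 2:
        raise ValueError("need at least 2 items")

    def _pairs(x: np.ndarray) -> int:
        _, counts = np.unique(x, return_counts=True)
        return int(np.sum(counts * (counts - 1) // 2))

    # contingency-table pair counts
    joint = np.unique(np.stack([pred, truth]), axis=1, return_counts=True)[1]
    tp = int(np.sum(joint * (joint - 1) // 2))
    same_pred = _pairs(pred)
    same_truth = _pairs(truth)
    fp = same_pred - tp
    fn = same_truth - tp
    total = n * (n - 1) // 2
    tn = total - tp - fp - fn
    return PartitionScore(tp=tp, tn=tn, fp=fp, fn=fn)
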