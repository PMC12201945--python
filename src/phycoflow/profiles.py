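"""Clustering of isolate consumption/production profiles and phylogenetic
signal testing.

Isolates are compared on their signed log2 fold-change vectors (entries of
non-significant features zeroed) with Euclidean distance, clustered
agglomeratively, and the resulting profile distances can be tested for
correlation with a phylogenetic distance matrix via a permutation Mantel
test. With few labels the Mantel null is enumerated exhaustively, making
the p-value exact.
"""

from __future__ import annotations

import logging
import math
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import (
    UNCHANGED,
    ConsumptionProfile,
    DistanceMatrix,
    ValidationError,
    align_profiles,
)

log = logging.getLogger(__name__)

__all__ = [
    "profile_distance",
    "hierarchical_cluster",
    "Dendrogram",
    "mantel_test",
]

#: Cap for |log2fc| when embedding profiles; +-inf sentinels (features
#: appearing from or vanishing to a zero mean) are clipped here.
LOG2FC_CAP = 10.0


def profile_distance(profiles: Sequence[ConsumptionProfile],
                     cap: float = LOG2FC_CAP) -> DistanceMatrix:
    """Euclidean distances between isolates' signed log2fc vectors.

    Non-significant (``unchanged``) entries are zeroed so distances
    reflect only called consumption/production; infinite fold changes are
    clipped to ``+-cap``. Distances are invariant to feature order.
    """
    profiles = align_profiles(profiles)
    if len(profiles) < 2:
        raise ValidationError("need >= 2 profiles")
    vectors = []
    for prof in profiles:
        lfc = prof.data["log2fc"].to_numpy(dtype=float)
        lfc = np.where(prof.data["call"].to_numpy() == UNCHANGED, 0.0, lfc)
        vectors.append(np.clip(lfc, -cap, cap))
    mat = np.vstack(vectors)
    dist = squareform(pdist(mat, metric="euclidean"))
    return DistanceMatrix([p.isolate for p in profiles], dist)


class Dendrogram:
    """Result of an agglomerative clustering: labels plus a scipy linkage.

    Labels are sorted lexicographically before linkage so that tie-breaking
    (and therefore merge order) is deterministic and independent of input
    order.
    """

    def __init__(self, labels: Sequence[str], linkage_matrix: np.ndarray,
                 method: str):
        self.labels = list(labels)
        self.linkage = linkage_matrix
        self.method = method

    @property
    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Successive merges as (left label set, right label set, height)."""
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = []
        n = len(self.labels)
        for k, (i, j, height, _) in enumerate(self.linkage):
            left, right = clusters[int(i)], clusters[int(j)]
            out.append((left, right, float(height)))
            clusters[n + k] = left | right
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        inner = rec(tree, tree.dist)
        # Root has zero-length stem; strip it.
        return f"{inner.rsplit(':', 1)[0]};"


def hierarchical_cluster(dist: DistanceMatrix,
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a labelled distance matrix.

    ``linkage`` is any scipy linkage method (``average`` default, the
    usual choice for profile heatmaps). NaN distances are rejected.
    """
    if not np.all(np.isfinite(dist.values)):
        raise ValidationError("distances must be finite for clustering")
    ordered = dist.reorder(sorted(dist.labels))
    condensed = squareform(ordered.values, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(ordered.labels, z, linkage)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _mantel_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(sps.pearsonr(x, y)[0])
    if method == "spearman":
        return float(sps.spearmanr(x, y)[0])
    raise ValidationError(f"unknown correlation method {method!r}")


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix,
                n_perm: int = 999, method: str = "pearson",
                alternative: str = "greater",
                seed: int | None = None) -> dict:
    """Permutation Mantel test between two labelled distance matrices.

    The statistic r is the correlation (Pearson default, Spearman
    optional) of the off-diagonal upper-triangle entries; the null is
    generated by permuting the labels of the second matrix. When the
    number of label permutations does not exceed ``n_perm`` the null is
    enumerated exhaustively (including the identity) and the p-value is
    the exact tail probability; otherwise ``n_perm`` random permutations
    are drawn and p = (1 + #{r_perm >= r_obs}) / (1 + n_perm). One-sided
    (positive association) by default; ``alternative="two-sided"`` compares
    |r|. Returns ``{r, p, n_perm, exact}``.
    """
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices must share labels; "
                              "reorder first")
    if n_perm < 99:
        raise ValidationError("need n_perm >= 99")
    n = len(d1.labels)
    x = _upper(d1.values)
    y = _upper(d2.values)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant distance matrix; correlation "
                              "undefined")
    r_obs = _mantel_r(x, y, method)
    eps = 1e-12

    def perm_r(order: np.ndarray) -> float:
        return _mantel_r(x, _upper(d2.values[np.ix_(order, order)]), method)

    def tail(r_p: float) -> bool:
        if alternative == "greater":
            return r_p >= r_obs - eps
        if alternative == "two-sided":
            return abs(r_p) >= abs(r_obs) - eps
        raise ValidationError(f"unknown alternative {alternative!r}")

    n_total = math.factorial(n)
    if n_total <= n_perm:
        count = sum(tail(perm_r(np.array(order)))
                    for order in permutations(range(n)))
        p = count / n_total
        return {"r": r_obs, "p": float(p), "n_perm": n_total, "exact": True}
    rng = np.random.default_rng(seed)
    count = sum(tail(perm_r(rng.permutation(n))) for _ in range(n_perm))
    p = (1 + count) / (1 + n_perm)
    return {"r": r_obs, "p": float(p), "n_perm": n_perm, "exact": False}
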