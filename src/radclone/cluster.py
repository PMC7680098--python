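"""Genetic distances, hierarchical clustering and clone calling."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .recode import RecodedGenotypeMatrix

LINKAGE_METHODS = ("complete", "average", "single")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix must be {n}x{n}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over labeled leaves."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.sample_ids[i] for i in order]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise merge heights, the tree's own distance structure."""
        coph = squareform(hierarchy.cophenet(self.linkage_matrix))
        return DistanceMatrix(sample_ids=list(self.sample_ids), values=coph,
                              metric=f"cophenetic[{self.method}]")

    def to_newick(self) -> str:
        """Newick string; branch lengths are differences of merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class ClonePairSet:
    """Unordered sample pairs at genetic distance <= epsilon."""

    pairs: list[tuple]
    epsilon: float

    def __post_init__(self) -> None:
        self.pairs = sorted({tuple(sorted(p)) for p in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in set(self.pairs)


def genetic_distance_matrix(m: RecodedGenotypeMatrix,
                            normalized: bool = False) -> DistanceMatrix:
    """Euclidean distance between recoded genotype columns.

    Raw (not per-site-normalized) by default, matching distances computed
    directly on the call vectors; ``normalized=True`` divides by sqrt(number
    of sites) so values are comparable across site sets.
    """
    if m.n_samples < 2:
        raise ValueError("need at least two samples for a distance matrix")
    if m.n_sites < 1:
        raise ValueError("need at least one site for a distance matrix")
    d = squareform(pdist(m.values.T, metric="euclidean"))
    metric = "euclidean"
    if normalized:
        d = d / np.sqrt(m.n_sites)
        metric = "euclidean/sqrt(n_sites)"
    return DistanceMatrix(sample_ids=list(m.sample_ids), values=d, metric=metric)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the distance matrix.

    Complete linkage by default; "average" and "single" are available.  The
    agglomeration order at exactly tied heights follows scipy's deterministic
    nearest-neighbor-chain algorithm.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if not np.isfinite(d.values).all():
        raise ValueError("distance matrix contains non-finite values")
    z = hierarchy.linkage(d.condensed(), method=linkage)
    return Dendrogram(sample_ids=list(d.sample_ids), linkage_matrix=z, method=linkage)


def call_clones(d: DistanceMatrix, epsilon: float = 0.0) -> ClonePairSet:
    """All unordered sample pairs with genetic distance <= epsilon.

    Error-free data from a clonal genet gives distance exactly 0, so the
    default threshold is 0; for noisy data see :func:`recommended_epsilon`.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    pairs = [
        (a, b)
        for (i, a), (j, b) in combinations(enumerate(d.sample_ids), 2)
        if d.values[i, j] <= epsilon
    ]
    return ClonePairSet(pairs=pairs, epsilon=epsilon)


def recommended_epsilon(d: DistanceMatrix, sheet, percentile: float = 1.0) -> float:
    """Suggested clone threshold: a low percentile (default 1st) of the
    between-circle distance distribution.  Reported for the caller to apply
    explicitly, never applied silently."""
    circle = sheet.circle_of()
    between = [
        d.values[i, j]
        for (i, a), (j, b) in combinations(enumerate(d.sample_ids), 2)
        if circle[a] != circle[b]
    ]
    if not between:
        raise ValueError("no between-circle pairs to calibrate epsilon from")
    return float(np.percentile(between, percentile))
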