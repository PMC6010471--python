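"""Hierarchical similarity trees with ordinary-bootstrap clade support.

Agglomeration uses Ward linkage on a precomputed distance matrix, which is
the same criterion R's ``hclust(method = "ward.D2")`` applies (squared
distances inside the Ward update, heights on the distance scale).  Support
values are ordinary bootstrap proportions: features are resampled with
replacement, the tree rebuilt, and each internal node's support is the
fraction of resampled trees containing the same leaf set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ContractError

# a distance function maps an (items x features) matrix to a condensed
# distance vector over items, as scipy.spatial.distance.pdist does
DistanceFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class ClusterTree:
    """Dendrogram over labelled items: scipy linkage matrix, leaf labels,
    and optional per-internal-node bootstrap support in [0, 1]."""

    linkage: np.ndarray
    labels: list[str]
    supports: dict[frozenset[str], float] | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ContractError("linkage shape inconsistent with label count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ContractError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self) -> list[frozenset[str]]:
        """Leaf set of every internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = [frozenset([lab]) for lab in self.labels]
        out: list[frozenset[str]] = []
        for a, b, _, _ in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def contains_clade(self, leaves: set[str] | frozenset[str]) -> bool:
        return frozenset(leaves) in set(self.clades())

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights and
        bootstrap supports as internal node labels."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        sets: list[frozenset[str]] = [frozenset([lab]) for lab in self.labels]
        text = {i: _escape(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + k
            parts = []
            for child in (a, b):
                parts.append(f"{text[child]}:{max(h - height[child], 0.0):.6g}")
            merged = sets[a] | sets[b]
            sets.append(merged)
            label = ""
            if self.supports is not None and merged in self.supports:
                label = f"{self.supports[merged]:.3g}"
            text[node] = f"({','.join(parts)}){label}"
            height[node] = float(h)
        return text[2 * n - 2] + ";"


def _escape(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def ward_tree(dist_condensed: np.ndarray, labels: list[str]) -> ClusterTree:
    """Ward (ward.D2-style) agglomeration on a condensed distance vector."""
    if len(labels) < 2:
        raise ContractError("need at least two items to build a tree")
    Z = linkage(dist_condensed, method="ward")
    return ClusterTree(Z, list(labels))


def bootstrap_tree(
    features: np.ndarray,
    labels: list[str],
    distance_fn: DistanceFn,
    nboot: int = 0,
    seed: int | np.random.Generator = 0,
) -> ClusterTree:
    """Build the tree on ``features`` (items x features) and, if nboot > 0,
    attach ordinary-bootstrap clade supports from feature resampling."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ContractError("features must be a 2-D items x features matrix")
    if features.shape[1] == 1:
        warnings.warn("single feature: tree is degenerate and supports are uninformative")
    tree = ward_tree(distance_fn(features), labels)
    if nboot <= 0:
        return tree
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {clade: 0 for clade in tree.clades()}
    nf = features.shape[1]
    for _ in range(nboot):
        resampled = features[:, rng.integers(0, nf, size=nf)]
        boot = ward_tree(distance_fn(resampled), labels)
        for clade in boot.clades():
            if clade in counts:
                counts[clade] += 1
    tree.supports = {clade: c / nboot for clade, c in counts.items()}
    return tree


def euclidean_condensed(features: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(features, metric="euclidean")


def condensed_to_square(d: np.ndarray) -> np.ndarray:
    return squareform(d)
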