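"""Hierarchical clustering of binarized IHC profiles.

Samples (and, symmetrically, markers) are represented by 0/1 positivity
vectors; distances are Euclidean on those vectors (the square root of the
Hamming distance) and trees are built by average linkage (UPGMA) with a
deterministic smallest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    Leaves are nodes 0..n-1; merge k creates node n+k joining ``merges[k] =
    (left, right, height)``. Within each merge the subtree containing the
    smaller original index comes first, which fixes the leaf order.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def _children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def _height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def leaf_order(self) -> list[int]:
        """Leaf indices in dendrogram display order."""
        if not self.merges:
            return list(range(self.n_leaves))
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            kids = self._children(node)
            if kids is None:
                order.append(node)
            else:
                stack.extend(reversed(kids))
        return order

    def leaf_labels(self) -> list[str]:
        labels = self.labels or [str(i) for i in range(self.n_leaves)]
        return [labels[i] for i in self.leaf_order()]

    def to_newick(self) -> str:
        """Newick serialization; branch length = parent height - child height."""
        labels = self.labels or [str(i) for i in range(self.n_leaves)]

        def render(node: int, parent_height: float) -> str:
            length = parent_height - self._height(node)
            kids = self._children(node)
            if kids is None:
                return f"{labels[node]}:{length:g}"
            inner = ",".join(render(k, self._height(node)) for k in kids)
            return f"({inner}):{length:g}"

        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return render(root, self._height(root)).rsplit(":", 1)[0] + ";"


def binary_profile(scores: pd.DataFrame) -> pd.DataFrame:
    """0/1 positivity matrix: 1 iff the IHC score is 2."""
    if scores.shape[1] == 0:
        raise ValueError("empty marker set")
    if not scores.isin((0, 1, 2)).all().all():
        raise ValueError("scores must be in {0, 1, 2}")
    return (scores == 2).astype(int)


def euclidean_binary(profile) -> np.ndarray:
    """Euclidean distances between binary rows: sqrt(Hamming count)."""
    x = np.asarray(profile, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("profile must be binary")
    hamming = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    return np.sqrt(hamming)


def average_linkage(dist: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA agglomeration of a distance matrix.

    The inter-cluster distance is the unweighted mean of all cross-pair
    distances. Ties between candidate merges are broken by the smallest
    original item index contained in the clusters (then the second
    smallest), making the tree deterministic.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 0:
        raise ValueError("dist must be a symmetric matrix with zero diagonal")

    # active clusters: node id -> (representative = min leaf index, size)
    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return dmat[(i, j) if i < j else (j, i)]

    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        nodes = sorted(active, key=lambda k: active[k][0])
        best = None
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                i, j = nodes[ai], nodes[bi]
                key = (get(i, j), active[i][0], active[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_height, _r1, _r2), i, j = best
        height = get(i, j)
        left, right = (i, j) if active[i][0] < active[j][0] else (j, i)
        size_i, size_j = active[i][1], active[j][1]
        for k in active:
            if k in (i, j):
                continue
            new = (size_i * get(i, k) + size_j * get(j, k)) / (size_i + size_j)
            dmat[(min(k, next_node), max(k, next_node))] = new
        active[next_node] = (min(active[i][0], active[j][0]), size_i + size_j)
        del active[i], active[j]
        merges.append((left, right, float(height)))
        next_node += 1
    return Dendrogram(n_leaves=n, merges=merges, labels=labels)


def cluster_profiles(
    scores: pd.DataFrame,
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Cluster samples and markers from an IHC score table.

    Both axes use Euclidean distance over the binarized profiles. Returns
    (sample tree, marker tree, binary profile).
    """
    profile = binary_profile(scores)
    sample_tree = average_linkage(
        euclidean_binary(profile.values), labels=list(profile.index)
    )
    marker_tree = average_linkage(
        euclidean_binary(profile.values.T), labels=list(profile.columns)
    )
    return sample_tree, marker_tree, profile


def heatmap_order(
    scores: pd.DataFrame, sample_tree: Dendrogram, marker_tree: Dendrogram
) -> pd.DataFrame:
    """Permute the score matrix to the dendrogram leaf orders for export."""
    sample_order = sample_tree.leaf_labels()
    marker_order = marker_tree.leaf_labels()
    if set(sample_order) != set(scores.index) or set(marker_order) != set(
        scores.columns
    ):
        raise ValueError("trees do not match the score table's samples/markers")
    return scores.loc[sample_order, marker_order]
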