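"""Ontology-anchored weighted k-means and silhouette evaluation.

Anchor terms (short ontology category phrases embedded in the same space
as the items) join the k-means point set as weighted pseudo-points that
pull centroids toward clinically meaningful regions.  An anchor weight
``w`` assigns total mass ``w * n_items`` to the anchor population, split
equally among anchors, so ``w = 0.5`` means the ontology counts half as
much as the data and ``w = 0`` reproduces plain item-only k-means.

Clustering quality is scored with the mean silhouette over *items only*
(anchors are guides, not observations), using Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples as _sk_silhouette_samples
from sklearn.metrics import silhouette_score as _sk_silhouette_score

from .embedding import EmbeddingMatrix

__all__ = [
    "WeightedPointSet",
    "AnchoredKMeans",
    "AnchoredKMeansResults",
    "build_weighted_points",
    "weighted_kmeans",
    "silhouette",
    "silhouette_samples",
]


@dataclass
class WeightedPointSet:
    """Items followed by anchors, each with a positive clustering weight."""

    X: np.ndarray
    weights: np.ndarray
    is_anchor: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.weights) == len(self.is_anchor) == len(self.ids)):
            raise ValueError("point set components must be row-aligned")
        if np.any(self.weights <= 0):
            raise ValueError("all weights must be positive")

    @property
    def n_items(self) -> int:
        return int((~self.is_anchor).sum())


def build_weighted_points(
    items: EmbeddingMatrix, anchors: EmbeddingMatrix | None, anchor_weight: float
) -> WeightedPointSet:
    """Stack items (weight 1 each) and anchors (total weight
    ``anchor_weight * n_items`` split equally).  ``anchor_weight = 0``
    excludes anchors entirely."""
    if anchor_weight < 0:
        raise ValueError("anchor_weight must be >= 0")
    n = len(items)
    if anchor_weight == 0 or anchors is None or len(anchors) == 0:
        if anchor_weight > 0:
            raise ValueError("anchor_weight > 0 requires a non-empty anchor matrix")
        return WeightedPointSet(
            X=items.X.copy(),
            weights=np.ones(n),
            is_anchor=np.zeros(n, dtype=bool),
            ids=list(items.ids),
        )
    if anchors.dim != items.dim:
        raise ValueError(f"dimension mismatch: items {items.dim}, anchors {anchors.dim}")
    m = len(anchors)
    per_anchor = anchor_weight * n / m
    return WeightedPointSet(
        X=np.vstack([items.X, anchors.X]),
        weights=np.concatenate([np.ones(n), np.full(m, per_anchor)]),
        is_anchor=np.concatenate([np.zeros(n, dtype=bool), np.ones(m, dtype=bool)]),
        ids=list(items.ids) + list(anchors.ids),
    )


class AnchoredKMeans:
    """Weighted k-means model over item embeddings with optional anchors.

    Parameters
    ----------
    items : EmbeddingMatrix
        Reduced item vectors to cluster.
    anchors : EmbeddingMatrix, optional
        Anchor-term vectors in the same space.
    k : int
        Number of clusters (>= 2).
    anchor_weight : float
        Total anchor mass as a fraction of item mass.
    n_init, max_iter, tol, seed
        k-means++ restarts (lowest-inertia solution kept), Lloyd iteration
        cap, convergence tolerance and random seed.
    """

    def __init__(
        self,
        items: EmbeddingMatrix,
        anchors: EmbeddingMatrix | None = None,
        *,
        k: int = 8,
        anchor_weight: float = 0.0,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        seed: int = 0,
    ):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.items = items
        self.anchors = anchors
        self.k = k
        self.anchor_weight = anchor_weight
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self) -> "AnchoredKMeansResults":
        points = build_weighted_points(self.items, self.anchors, self.anchor_weight)
        if self.k > len(points.X):
            raise ValueError(f"k={self.k} exceeds number of points ({len(points.X)})")
        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.seed,
        )
        labels = km.fit_predict(points.X, sample_weight=points.weights)
        item_mask = ~points.is_anchor
        assignments = {
            i: int(c) for i, c in zip(np.array(points.ids)[item_mask], labels[item_mask])
        }
        anchor_assignments = {
            i: int(c) for i, c in zip(np.array(points.ids)[~item_mask], labels[~item_mask])
        }
        return AnchoredKMeansResults(
            model=self,
            assignments=assignments,
            anchor_assignments=anchor_assignments,
            centroids=km.cluster_centers_,
            inertia=float(km.inertia_),
        )


@dataclass
class AnchoredKMeansResults:
    """Fitted clustering: item assignments, centroids and quality scores."""

    model: AnchoredKMeans
    assignments: dict[str, int]
    anchor_assignments: dict[str, int]
    centroids: np.ndarray
    inertia: float
    params: Mapping | None = None
    heuristic_score: float | None = None
    _silhouette: float | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return list(self.assignments)

    def labels(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = ids if ids is not None else self.item_ids
        return np.array([self.assignments[i] for i in ids])

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels()).value_counts().sort_index()

    @property
    def silhouette(self) -> float:
        if self._silhouette is None:
            self._silhouette = silhouette(self.model.items, self.assignments)
        return self._silhouette

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        lines = [
            "Anchored weighted k-means",
            "=" * 41,
            f"items            {len(self.assignments)}",
            f"anchors          {len(self.anchor_assignments)}",
            f"k                {self.k}",
            f"anchor weight    {self.model.anchor_weight}",
            f"inertia          {self.inertia:.4f}",
            f"silhouette       {self.silhouette:.4f}",
            f"cluster sizes    min {sizes.min()}, median {int(sizes.median())}, max {sizes.max()}",
        ]
        return "\n".join(lines)

    def plot_sizes(self, ax=None):  # pragma: no cover - thin matplotlib wrapper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.cluster_sizes().plot.bar(ax=ax)
        ax.set_xlabel("cluster")
        ax.set_ylabel("items")
        return ax


def weighted_kmeans(
    points: WeightedPointSet, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Functional form: cluster a prepared weighted point set.

    Returns (labels over all points, centroids, weighted inertia).
    """
    if k > len(points.X):
        raise ValueError(f"k={k} exceeds number of points ({len(points.X)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6, random_state=seed)
    labels = km.fit_predict(points.X, sample_weight=points.weights)
    return labels, km.cluster_centers_, float(km.inertia_)


def _as_label_array(
    points: EmbeddingMatrix, assignments: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    ids = [i for i in points.ids if i in assignments]
    sub = points.subset(ids)
    return sub.X, np.array([assignments[i] for i in ids])


def silhouette(points: EmbeddingMatrix, assignments: Mapping[str, int]) -> float:
    """Mean silhouette over items, Euclidean distance; in [-1, 1].

    Raises on fewer than two distinct clusters (undefined).
    """
    X, labels = _as_label_array(points, assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(_sk_silhouette_score(X, labels, metric="euclidean"))


def silhouette_samples(points: EmbeddingMatrix, assignments: Mapping[str, int]) -> pd.Series:
    """Per-item silhouette values, indexed by item id."""
    ids = [i for i in points.ids if i in assignments]
    X, labels = _as_label_array(points, assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return pd.Series(_sk_silhouette_samples(X, labels, metric="euclidean"), index=ids)
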