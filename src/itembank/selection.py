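"""Hyperparameter grid search over anchored clusterings.

One clustering is generated for every combination of cluster count
``k``, word filter, PCA target dimension and anchor weight; each is
scored by an automatic heuristic (silhouette, or agreement with expert
annotations once those exist) and only the best few are retained for
human review.  The automatic heuristic weeds out underfitting
clusterings; the human pass afterwards catches clusterings that score
well but mean little — neither alone is reliable on unsupervised text.

Embeddings and PCA fits are shared across the grid: items are embedded
once per word filter and reduced once per (filter, dimension), so the
grid cost is dominated by the k-means runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import AnchoredKMeans, AnchoredKMeansResults
from .corpus import Corpus, Item
from .embedding import (
    EmbedderBackend,
    EmbeddingMatrix,
    HashingBackend,
    WordFilterSpec,
    corpus_word_counts,
    embed_sentences,
    fit_reduce,
)
from .metrics import AnnotationSet, label_f1, pairwise_accuracy

__all__ = ["HyperParams", "ParamGrid", "ClusteringGridSearch", "GridSearchResults", "HEURISTICS"]

DEFAULT_FILTERS = (
    WordFilterSpec("none"),
    WordFilterSpec("min_length"),
    WordFilterSpec("stopword"),
    WordFilterSpec("frequency"),
)


@dataclass(frozen=True)
class HyperParams:
    """One grid point: cluster count, word filter, PCA dim, anchor weight."""

    k: int
    word_filter: WordFilterSpec = WordFilterSpec("none")
    target_dim: int = 25
    anchor_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.anchor_weight < 0:
            raise ValueError("anchor_weight must be >= 0")

    def sort_key(self) -> tuple:
        return (self.k, self.word_filter.kind, self.target_dim, self.anchor_weight)


@dataclass(frozen=True)
class ParamGrid:
    """Cartesian hyperparameter ranges; defaults follow the standard sweep
    (k from 4 to 40, four word filters, PCA dims {5, 10, 25, 50}, anchor
    weights {0, 0.1, 0.25, 0.5})."""

    k_values: tuple[int, ...] = tuple(range(4, 41))
    filters: tuple[WordFilterSpec, ...] = DEFAULT_FILTERS
    dims: tuple[int, ...] = (5, 10, 25, 50)
    anchor_weights: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5)

    def combinations(self, seed: int = 0) -> list[HyperParams]:
        return [
            HyperParams(k=k, word_filter=f, target_dim=d, anchor_weight=w, seed=seed)
            for f, d, w, k in product(self.filters, self.dims, self.anchor_weights, self.k_values)
        ]

    def __len__(self) -> int:
        return len(self.k_values) * len(self.filters) * len(self.dims) * len(self.anchor_weights)


HEURISTICS = ("silhouette", "pair_accuracy", "pair_and_label_accuracy")


class ClusteringGridSearch:
    """Enumerate the grid, score every clustering, retain the best few.

    Parameters
    ----------
    corpus : Corpus or sequence of Item
        Cleaned items (tokens populated).
    anchor_terms : sequence of str
        Ontology anchor phrases; may be empty if every grid anchor weight
        is zero.
    grid : ParamGrid
    backend : EmbedderBackend
        Sentence encoder (deterministic hashing by default).
    heuristic : {"silhouette", "pair_accuracy", "pair_and_label_accuracy"}
        Automatic score used for ranking; the annotation-based heuristics
        require ``annotations``.
    annotations : AnnotationSet, optional
    transform : ndarray, optional
        Linear refinement applied to the base embedding space (items and
        anchors alike) before PCA.
    seed : int
        Seeds k-means for every grid point.
    """

    def __init__(
        self,
        corpus: Corpus | Sequence[Item],
        anchor_terms: Sequence[str] = (),
        grid: ParamGrid = ParamGrid(),
        *,
        backend: EmbedderBackend | None = None,
        heuristic: str = "silhouette",
        annotations: AnnotationSet | None = None,
        transform: np.ndarray | None = None,
        seed: int = 0,
        n_init: int = 10,
    ):
        if heuristic not in HEURISTICS:
            raise ValueError(f"heuristic must be one of {HEURISTICS}, got {heuristic!r}")
        if heuristic != "silhouette" and (annotations is None or not annotations.pairs):
            raise ValueError(f"heuristic {heuristic!r} requires pair annotations")
        if heuristic == "pair_and_label_accuracy" and not (annotations and annotations.labels):
            raise ValueError("pair_and_label_accuracy requires label annotations")
        self.items = list(corpus.items if isinstance(corpus, Corpus) else corpus)
        self.anchor_terms = list(anchor_terms)
        if not self.anchor_terms and any(w > 0 for w in grid.anchor_weights):
            raise ValueError("grid includes positive anchor weights but no anchor terms given")
        self.grid = grid
        self.backend = backend if backend is not None else HashingBackend()
        self.heuristic = heuristic
        self.annotations = annotations
        self.transform = transform
        self.seed = seed
        self.n_init = n_init

    # -- embedding caches -------------------------------------------------
    def _base_embeddings(self, word_filter: WordFilterSpec) -> tuple[EmbeddingMatrix, EmbeddingMatrix]:
        counts = corpus_word_counts(self.items)
        items = embed_sentences(self.items, self.backend, word_filter, counts)
        anchors = embed_sentences(
            [
                Item(
                    id=f"anchor{j:03d}",
                    source_measure="ontology",
                    raw_text=t,
                    normalized_text=t.lower(),
                    tokens=tuple(t.lower().split()),
                )
                for j, t in enumerate(self.anchor_terms)
            ],
            self.backend,
            word_filter,
            counts,
        )
        if self.transform is not None:
            items = EmbeddingMatrix(items.ids, items.X @ self.transform.T, items.backend_name)
            if len(anchors):
                anchors = EmbeddingMatrix(
                    anchors.ids, anchors.X @ self.transform.T, anchors.backend_name
                )
        return items, anchors

    def _reduced(
        self, cache: dict, word_filter: WordFilterSpec, dim: int
    ) -> tuple[EmbeddingMatrix, EmbeddingMatrix]:
        key = (word_filter, dim)
        if key not in cache:
            base_key = ("base", word_filter)
            if base_key not in cache:
                cache[base_key] = self._base_embeddings(word_filter)
            items, anchors = cache[base_key]
            # PCA is fitted on the union so anchors live in the same space
            union = EmbeddingMatrix(
                items.ids + anchors.ids,
                np.vstack([items.X, anchors.X]) if len(anchors) else items.X,
                items.backend_name,
            )
            _, reduced = fit_reduce(union, dim, seed=self.seed)
            cache[key] = (reduced.subset(items.ids), reduced.subset(anchors.ids))
        return cache[key]

    # -- scoring ----------------------------------------------------------
    def _score(self, results: AnchoredKMeansResults) -> float:
        if self.heuristic == "silhouette":
            return results.silhouette
        assert self.annotations is not None
        acc = pairwise_accuracy(results, self.annotations.pairs)
        if self.heuristic == "pair_accuracy":
            return acc
        return 0.5 * (acc + label_f1(results, self.annotations.labels))

    def fit(self, retain: int = 10) -> "GridSearchResults":
        combos = self.grid.combinations(seed=self.seed)
        if retain > len(combos):
            warnings.warn(
                f"retain={retain} exceeds grid size {len(combos)}; returning all",
                stacklevel=2,
            )
        cache: dict = {}
        fitted: list[AnchoredKMeansResults] = []
        for hp in combos:
            items_red, anchors_red = self._reduced(cache, hp.word_filter, hp.target_dim)
            model = AnchoredKMeans(
                items_red,
                anchors_red if hp.anchor_weight > 0 else None,
                k=hp.k,
                anchor_weight=hp.anchor_weight,
                n_init=self.n_init,
                seed=self.seed,
            )
            res = model.fit()
            res.params = hp
            res.heuristic_score = self._score(res)
            fitted.append(res)
        order = sorted(
            range(len(fitted)),
            key=lambda i: (-fitted[i].heuristic_score, *combos[i].sort_key()),
        )
        retained = [fitted[i] for i in order[:retain]]
        return GridSearchResults(
            search=self, all_clusterings=fitted, retained=retained
        )


@dataclass
class GridSearchResults:
    """Every fitted clustering plus the retained short-list.

    ``table()`` mirrors the usual reporting layout: one row per retained
    clustering with K, word filtering, PCA dimension, anchor weight and
    scores.  ``full_table()`` logs the whole grid.
    """

    search: ClusteringGridSearch
    all_clusterings: list[AnchoredKMeansResults]
    retained: list[AnchoredKMeansResults]

    @property
    def best(self) -> AnchoredKMeansResults:
        return self.retained[0]

    def select(self, index: int = 0) -> AnchoredKMeansResults:
        """Expert override hook: pick any of the retained clusterings."""
        return self.retained[index]

    def _rows(self, results: Sequence[AnchoredKMeansResults]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Clustering": range(1, len(results) + 1),
                "K": [r.params.k for r in results],
                "Word filtering": [r.params.word_filter.label for r in results],
                "PCA dimension": [r.params.target_dim for r in results],
                "Anchor weight": [r.params.anchor_weight for r in results],
                "Heuristic": [r.heuristic_score for r in results],
                "Silhouette score": [r.silhouette for r in results],
            }
        )

    def table(self) -> pd.DataFrame:
        return self._rows(self.retained)

    def full_table(self) -> pd.DataFrame:
        return self._rows(self.all_clusterings)

    def summary(self) -> str:
        best = self.best
        lines = [
            f"Grid search: {len(self.all_clusterings)} clusterings, "
            f"heuristic = {self.search.heuristic}",
            "=" * 60,
            self.table().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"best: k={best.params.k}, filter={best.params.word_filter.kind}, "
            f"dim={best.params.target_dim}, anchor weight={best.params.anchor_weight}",
        ]
        return "\n".join(lines)

    def plot_heuristic_by_k(self, ax=None):  # pragma: no cover - plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.full_table()
        for (filt, dim, w), sub in frame.groupby(
            ["Word filtering", "PCA dimension", "Anchor weight"]
        ):
            ax.plot(sub["K"], sub["Heuristic"], alpha=0.5, label=f"{filt}, d={dim}, w={w}")
        ax.set_xlabel("k")
        ax.set_ylabel(self.search.heuristic)
        return ax
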