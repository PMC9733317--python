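"""The iterative expert-in-the-loop clustering protocol.

Three rounds, each a full grid search followed by annotation:

1. **Round 1** — cluster the untouched embedding space; the only usable
   automatic heuristic is the silhouette.  Experts (or the simulated
   oracle) then review the items nearest each centroid and assert, for
   sampled pairs, whether the two items belong to the same domain.
2. **Round 2** — the pair relations train a linear refinement of the
   embedding space; the grid search repeats with pair accuracy as the
   heuristic.  Experts then label the reviewed items with domains.
3. **Round 3** — the space is refined again on pairs plus label-derived
   relations; the heuristic averages pair accuracy and label agreement.

Annotations accumulate: later rounds never discard earlier constraints.
Each round's selected clustering is scored post hoc with E1 (pair F1
against the collected pair relations) and E2 (macro label F1 against
the collected labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol as _Protocol, Sequence

import numpy as np
import pandas as pd

from .cluster import AnchoredKMeansResults
from .corpus import Corpus
from .embedding import (
    EmbedderBackend,
    EmbeddingMatrix,
    HashingBackend,
    corpus_word_counts,
    embed_sentences,
)
from .metrics import AnnotationSet, PairAnnotation, label_f1, pair_annotation_f1
from .refine import ConstraintRefiner, RefinementResults
from .selection import ClusteringGridSearch, GridSearchResults, ParamGrid

__all__ = [
    "AnnotationOracle",
    "ReplayOracle",
    "MissingAnnotationsError",
    "IterativeProtocol",
    "ProtocolResults",
    "RoundResult",
]

ROUND_HEURISTICS = {1: "silhouette", 2: "pair_accuracy", 3: "pair_and_label_accuracy"}


class AnnotationOracle(_Protocol):
    def same_domain(self, item_a: str, item_b: str) -> bool: ...

    def label(self, item_id: str) -> str: ...


class MissingAnnotationsError(RuntimeError):
    """An annotation source could not answer a query required by a round."""


class ReplayOracle:
    """Answers annotation queries from previously collected CSV files
    (pair file: item_a,item_b,same_domain; label file: item,domain_label).
    Unknown queries raise :class:`MissingAnnotationsError`."""

    def __init__(self, pair_file: str | Path | None = None, label_file: str | Path | None = None):
        self._pairs: dict[tuple[str, str], bool] = {}
        self._labels: dict[str, str] = {}
        if pair_file is not None:
            for p in AnnotationSet.load_pairs(pair_file):
                self._pairs[p.key] = p.same_domain
        if label_file is not None:
            self._labels = AnnotationSet.load_labels(label_file)

    def same_domain(self, item_a: str, item_b: str) -> bool:
        key = tuple(sorted((item_a, item_b)))
        if key not in self._pairs:
            raise MissingAnnotationsError(f"no recorded pair annotation for {key}")
        return self._pairs[key]

    def label(self, item_id: str) -> str:
        if item_id not in self._labels:
            raise MissingAnnotationsError(f"no recorded label for {item_id!r}")
        return self._labels[item_id]


@dataclass
class RoundResult:
    round: int
    heuristic: str
    search: GridSearchResults
    best: AnchoredKMeansResults
    e1: float | None = None
    e2: float | None = None


class IterativeProtocol:
    """Orchestrates grid searches, annotation collection and refinement.

    Parameters
    ----------
    corpus : Corpus
        Cleaned corpus.
    anchor_terms : sequence of str
    oracle : AnnotationOracle
        Simulated oracle or replayed expert files; queried for pair
        relations after round 1 and labels after round 2.
    grid : ParamGrid
    backend : EmbedderBackend, optional
    retain : int
        Short-list size per grid search.
    review_depth : int
        Items nearest each centroid offered for annotation (the expert
        panel convention of reviewing the top 30 per cluster).
    pairs_within, pairs_between : int
        Pair queries sampled per cluster, inside and across clusters.
    select : int
        Index into the retained short-list to carry forward (0 = best by
        heuristic; an expert override hook).
    """

    def __init__(
        self,
        corpus: Corpus,
        anchor_terms: Sequence[str],
        oracle: AnnotationOracle,
        grid: ParamGrid,
        *,
        backend: EmbedderBackend | None = None,
        retain: int = 10,
        review_depth: int = 30,
        pairs_within: int = 5,
        pairs_between: int = 5,
        select: int = 0,
        refine_margin: float = 1.0,
        refine_epochs: int = 60,
        refine_rate: float = 0.5,
        n_init: int = 10,
        seed: int = 0,
    ):
        self.corpus = corpus
        self.anchor_terms = list(anchor_terms)
        self.oracle = oracle
        self.grid = grid
        self.backend = backend if backend is not None else HashingBackend()
        self.retain = retain
        self.review_depth = review_depth
        self.pairs_within = pairs_within
        self.pairs_between = pairs_between
        self.select = select
        self.refine_margin = refine_margin
        self.refine_epochs = refine_epochs
        self.refine_rate = refine_rate
        self.n_init = n_init
        self.seed = seed

    # -- annotation sampling ---------------------------------------------
    def reviewed_items(self, results: AnchoredKMeansResults) -> dict[int, list[str]]:
        """Per cluster, the ``review_depth`` items nearest the centroid."""
        ids = np.array(results.item_ids)
        X = results.model.items.subset(list(ids)).X
        labels = results.labels(list(ids))
        out: dict[int, list[str]] = {}
        for c in np.unique(labels):
            mask = labels == c
            dists = np.linalg.norm(X[mask] - results.centroids[c], axis=1)
            order = np.argsort(dists, kind="stable")[: self.review_depth]
            out[int(c)] = list(ids[mask][order])
        return out

    def _collect_pairs(
        self, results: AnchoredKMeansResults, round_no: int
    ) -> list[PairAnnotation]:
        rng = np.random.default_rng(self.seed * 1009 + round_no)
        reviewed = self.reviewed_items(results)
        clusters = sorted(reviewed)
        pairs: list[PairAnnotation] = []
        seen: set[tuple[str, str]] = set()

        def ask(a: str, b: str) -> None:
            key = tuple(sorted((a, b)))
            if a == b or key in seen:
                return
            seen.add(key)
            try:
                answer = self.oracle.same_domain(a, b)
            except MissingAnnotationsError as exc:
                raise MissingAnnotationsError(
                    f"round {round_no}: pair annotations unavailable ({exc})"
                ) from exc
            pairs.append(PairAnnotation(a, b, answer))

        for c in clusters:
            members = reviewed[c]
            if len(members) >= 2:
                for _ in range(self.pairs_within):
                    a, b = rng.choice(members, size=2, replace=False)
                    ask(str(a), str(b))
            others = [o for o in clusters if o != c and reviewed[o]]
            if others:
                for _ in range(self.pairs_between):
                    a = str(rng.choice(members))
                    b = str(rng.choice(reviewed[int(rng.choice(others))]))
                    ask(a, b)
        return pairs

    def _collect_labels(
        self, results: AnchoredKMeansResults, round_no: int
    ) -> dict[str, str]:
        labels: dict[str, str] = {}
        for members in self.reviewed_items(results).values():
            for item_id in members:
                try:
                    labels[item_id] = self.oracle.label(item_id)
                except MissingAnnotationsError as exc:
                    raise MissingAnnotationsError(
                        f"round {round_no}: label annotations unavailable ({exc})"
                    ) from exc
        return labels

    def _label_pairs(
        self, labels: Mapping[str, str], round_no: int
    ) -> list[PairAnnotation]:
        """Turn item labels into pair relations for refinement training."""
        rng = np.random.default_rng(self.seed * 2003 + round_no)
        ids = sorted(labels)
        by_label: dict[str, list[str]] = {}
        for i in ids:
            by_label.setdefault(labels[i], []).append(i)
        out: list[PairAnnotation] = []
        for i in ids:
            same = [j for j in by_label[labels[i]] if j != i]
            diff_labels = [lab for lab in by_label if lab != labels[i]]
            if same:
                out.append(PairAnnotation(i, str(rng.choice(same)), True))
            if diff_labels:
                lab = str(rng.choice(diff_labels))
                out.append(PairAnnotation(i, str(rng.choice(by_label[lab])), False))
        return out

    # -- the protocol ------------------------------------------------------
    def fit(self, rounds: int = 3) -> "ProtocolResults":
        if not 1 <= rounds <= 3:
            raise ValueError("rounds must be 1, 2 or 3")
        annotations = AnnotationSet.empty()
        refinements: list[RefinementResults] = []
        transform: np.ndarray | None = None
        round_results: list[RoundResult] = []
        for round_no in range(1, rounds + 1):
            heuristic = ROUND_HEURISTICS[round_no]
            if round_no == 2:
                if not annotations.pairs:
                    raise MissingAnnotationsError("round 2: no pair annotations collected")
                refinement = self._refine(annotations.pairs, transform)
                refinements.append(refinement)
                transform = refinement.transform
            elif round_no == 3:
                if not annotations.labels:
                    raise MissingAnnotationsError("round 3: no label annotations collected")
                training_pairs = list(annotations.pairs) + self._label_pairs(
                    annotations.labels, round_no
                )
                refinement = self._refine(training_pairs, transform)
                refinements.append(refinement)
                transform = refinement.compose(transform)

            search = ClusteringGridSearch(
                self.corpus,
                self.anchor_terms,
                self.grid,
                backend=self.backend,
                heuristic=heuristic,
                annotations=annotations if round_no > 1 else None,
                transform=transform,
                seed=self.seed,
                n_init=self.n_init,
            ).fit(retain=self.retain)
            best = search.select(self.select)
            round_results.append(
                RoundResult(round=round_no, heuristic=heuristic, search=search, best=best)
            )

            if round_no == 1 and rounds > 1:
                annotations.add_pairs(self._collect_pairs(best, round_no))
            elif round_no == 2 and rounds > 2:
                annotations.add_labels(self._collect_labels(best, round_no))

        for rr in round_results:
            if annotations.pairs:
                rr.e1 = pair_annotation_f1(rr.best, annotations.pairs)
            if annotations.labels:
                rr.e2 = label_f1(rr.best, annotations.labels)

        return ProtocolResults(
            protocol=self,
            rounds=round_results,
            annotations=annotations,
            refinements=refinements,
        )

    def _refine(
        self, pairs: Sequence[PairAnnotation], transform: np.ndarray | None
    ) -> RefinementResults:
        counts = corpus_word_counts(self.corpus)
        base = embed_sentences(self.corpus.items, self.backend, self.grid.filters[0], counts)
        if transform is not None:
            base = EmbeddingMatrix(base.ids, base.X @ transform.T, base.backend_name)
        usable_ids = set(base.ids)
        usable = [p for p in pairs if p.item_a in usable_ids and p.item_b in usable_ids]
        return ConstraintRefiner(
            base,
            usable,
            margin=self.refine_margin,
            learning_rate=self.refine_rate,
            epochs=self.refine_epochs,
            seed=self.seed,
        ).fit()


@dataclass
class ProtocolResults:
    """Per-round selected clusterings, accumulated annotations and
    refinement transforms."""

    protocol: IterativeProtocol
    rounds: list[RoundResult]
    annotations: AnnotationSet
    refinements: list[RefinementResults] = field(default_factory=list)

    @property
    def final(self) -> AnchoredKMeansResults:
        return self.rounds[-1].best

    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": [r.round for r in self.rounds],
                "heuristic": [r.heuristic for r in self.rounds],
                "heuristic_score": [r.best.heuristic_score for r in self.rounds],
                "k": [r.best.params.k for r in self.rounds],
                "silhouette": [r.best.silhouette for r in self.rounds],
                "E1_pair_f1": [r.e1 for r in self.rounds],
                "E2_label_f1": [r.e2 for r in self.rounds],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Iterative clustering protocol ({len(self.rounds)} rounds)",
            "=" * 58,
            self.scores().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"annotations: {len(self.annotations.pairs)} pair relations "
            f"({self.annotations.n_must_link} must-link), "
            f"{len(self.annotations.labels)} item labels",
        ]
        return "\n".join(lines)
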