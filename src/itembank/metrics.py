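"""Scoring clusterings against expert annotations and reference labels.

Two annotation currencies circulate in the pipeline:

* pairwise relations — an expert asserts that two items do or do not
  belong to the same domain (must-link / cannot-link);
* item labels — an expert assigns an item to an agreed-upon domain.

Three scores are built on them.  ``pairwise_accuracy`` is the fraction
of annotated pairs whose co-clustering status matches the assertion.
``pairwise_f1`` (E1) treats "predicted same cluster" as a positive
prediction and "same reference label" as a positive truth and computes
F1 over all labeled item pairs; it penalizes over-splitting since a
finer clustering loses recall on true pairs.  ``label_f1`` (E2) maps
each cluster to its majority reference label and macro-averages F1 over
the labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

__all__ = [
    "PairAnnotation",
    "AnnotationSet",
    "pairwise_accuracy",
    "pairwise_f1",
    "pair_annotation_f1",
    "label_f1",
    "majority_label_map",
]


@dataclass(frozen=True)
class PairAnnotation:
    """One expert judgment: do these two items measure the same domain?"""

    item_a: str
    item_b: str
    same_domain: bool

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise ValueError(f"pair annotation needs two distinct items, got {self.item_a!r}")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.item_a, self.item_b)))  # type: ignore[return-value]


@dataclass
class AnnotationSet:
    """Accumulated pair relations and item labels across expert rounds."""

    pairs: list[PairAnnotation]
    labels: dict[str, str]

    @classmethod
    def empty(cls) -> "AnnotationSet":
        return cls(pairs=[], labels={})

    def add_pairs(self, pairs: Iterable[PairAnnotation]) -> None:
        known = {p.key for p in self.pairs}
        for p in pairs:
            if p.key not in known:
                known.add(p.key)
                self.pairs.append(p)

    def add_labels(self, labels: Mapping[str, str]) -> None:
        self.labels.update(labels)

    @property
    def n_must_link(self) -> int:
        return sum(p.same_domain for p in self.pairs)

    @property
    def n_cannot_link(self) -> int:
        return len(self.pairs) - self.n_must_link

    def save_pairs(self, path: str | Path) -> None:
        pd.DataFrame(
            [(p.item_a, p.item_b, p.same_domain) for p in self.pairs],
            columns=["item_a", "item_b", "same_domain"],
        ).to_csv(path, index=False)

    def save_labels(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.labels.items()), columns=["item", "domain_label"]
        ).to_csv(path, index=False)

    @staticmethod
    def load_pairs(path: str | Path) -> list[PairAnnotation]:
        frame = pd.read_csv(path)
        return [
            PairAnnotation(str(r.item_a), str(r.item_b), bool(r.same_domain))
            for r in frame.itertuples()
        ]

    @staticmethod
    def load_labels(path: str | Path) -> dict[str, str]:
        frame = pd.read_csv(path)
        return dict(zip(frame["item"].astype(str), frame["domain_label"].astype(str)))


def _assignments_of(clustering) -> Mapping[str, int]:
    return clustering if isinstance(clustering, Mapping) else clustering.assignments


def pairwise_accuracy(clustering, pairs: Iterable[PairAnnotation]) -> float:
    """Fraction of annotated pairs whose same-cluster status matches the
    annotation.  Errors on an empty pair set."""
    assignments = _assignments_of(clustering)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pairwise_accuracy needs at least one annotated pair")
    hits = sum(
        (assignments[p.item_a] == assignments[p.item_b]) == p.same_domain for p in pairs
    )
    return hits / len(pairs)


def pair_annotation_f1(clustering, pairs: Iterable[PairAnnotation]) -> float:
    """Binary F1 on annotated pairs: positive prediction = co-clustered,
    positive truth = annotated same-domain.  0 when nothing is predicted
    positive."""
    assignments = _assignments_of(clustering)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pair_annotation_f1 needs at least one annotated pair")
    tp = fp = fn = 0
    for p in pairs:
        pred = assignments[p.item_a] == assignments[p.item_b]
        if pred and p.same_domain:
            tp += 1
        elif pred:
            fp += 1
        elif p.same_domain:
            fn += 1
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def pairwise_f1(clustering, truth: Mapping[str, str]) -> float:
    """Pair-level F1 of a clustering against reference labels (E1).

    Over all pairs of labeled items: precision = co-clustered pairs that
    share a true label / co-clustered pairs, recall = the same numerator /
    same-label pairs.  Computed from the cluster-by-label contingency
    table, so it scales to thousands of items.
    """
    assignments = _assignments_of(clustering)
    ids = [i for i in truth if i in assignments]
    if len(ids) < 2:
        raise ValueError("pairwise_f1 needs at least two labeled clustered items")
    table = pd.crosstab(
        pd.Series([assignments[i] for i in ids], name="cluster"),
        pd.Series([truth[i] for i in ids], name="label"),
    ).to_numpy()

    def pairs2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    tp = pairs2(table)
    pred_pos = pairs2(table.sum(axis=1))
    true_pos = pairs2(table.sum(axis=0))
    if pred_pos == 0:
        return 0.0
    if true_pos == 0:
        return 0.0 if pred_pos else 1.0
    precision = tp / pred_pos
    recall = tp / true_pos
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def majority_label_map(clustering, truth: Mapping[str, str]) -> dict[int, str]:
    """Map each cluster to its majority reference label; ties break to the
    lexicographically smallest label (deterministic)."""
    assignments = _assignments_of(clustering)
    votes: dict[int, Counter] = {}
    for i, lab in truth.items():
        if i in assignments:
            votes.setdefault(assignments[i], Counter())[lab] += 1
    return {
        c: min(cnt, key=lambda lab: (-cnt[lab], lab)) for c, cnt in votes.items()
    }


def label_f1(clustering, truth: Mapping[str, str]) -> float:
    """Macro-averaged label F1 (E2) after majority-mapping clusters to labels."""
    assignments = _assignments_of(clustering)
    ids = [i for i in truth if i in assignments]
    if not ids:
        raise ValueError("label_f1 needs at least one labeled clustered item")
    mapping = majority_label_map(clustering, truth)
    y_true = [truth[i] for i in ids]
    y_pred = [mapping[assignments[i]] for i in ids]
    label_set = sorted(set(y_true))
    return float(
        f1_score(y_true, y_pred, labels=label_set, average="macro", zero_division=0)
    )
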