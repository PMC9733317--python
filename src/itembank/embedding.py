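"""Word filtering, sentence embedding and PCA reduction.

Items (and ontology anchor terms) are turned into real-valued vectors in
three stages:

1. a word filter applied to the normalized token list — no filter,
   minimum word length, stop-word removal, or corpus-frequency removal;
2. a pluggable sentence-embedding backend mapping the filtered sentence
   to a fixed-dimension vector (768 by default, matching the output
   width of standard pre-trained sentence-transformer encoders);
3. PCA down to a small working dimension, since distance-based
   clustering degrades badly in hundreds of dimensions.

The default backend hashes character n-grams of the filtered sentence
into 768 dimensions.  It is fully deterministic and needs no model
download, so the whole pipeline is reproducible from a seed; sentences
sharing vocabulary land near each other, which is the property the
downstream clustering relies on.  A sentence-transformer backend can be
plugged in where the optional dependency is installed.

Anchor terms must travel through the *same* filter, backend and fitted
reduction as the items so that both populations live in one comparable
space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS, HashingVectorizer

from .corpus import Corpus, Item

__all__ = [
    "WordFilterSpec",
    "EmbeddingMatrix",
    "EmbedderBackend",
    "HashingBackend",
    "TransformerBackend",
    "ReductionModel",
    "apply_word_filter",
    "corpus_word_counts",
    "embed_sentences",
    "embed_anchor_terms",
    "fit_reduce",
    "get_backend",
]

FILTER_KINDS = ("none", "min_length", "stopword", "frequency")


@dataclass(frozen=True)
class WordFilterSpec:
    """Which word filter to apply before embedding.

    ``kind`` selects the active rule; the remaining fields parameterize it.
    ``min_length`` drops words with fewer than ``min_letters`` letters,
    ``stopword`` drops words in ``stopword_list``, and ``frequency`` drops
    words occurring ``max_occurrence`` times or more in the whole corpus
    (words seen too often carry little domain signal).
    """

    kind: str = "none"
    min_letters: int = 4
    stopword_list: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)
    max_occurrence: int = 20

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}; expected one of {FILTER_KINDS}")
        if self.min_letters < 1:
            raise ValueError("min_letters must be >= 1")
        if self.max_occurrence < 1:
            raise ValueError("max_occurrence must be >= 1")

    @property
    def label(self) -> str:
        return {
            "none": "None",
            "min_length": f"Words with < {self.min_letters} letters removed",
            "stopword": "Stop words removed",
            "frequency": f"Words present >= {self.max_occurrence} times removed",
        }[self.kind]


def corpus_word_counts(corpus: Corpus | Iterable[Item]) -> Counter:
    items = corpus.items if isinstance(corpus, Corpus) else corpus
    counts: Counter = Counter()
    for it in items:
        counts.update(it.tokens)
    return counts


def apply_word_filter(
    tokens: Sequence[str],
    spec: WordFilterSpec,
    corpus_counts: Counter | dict[str, int] | None = None,
) -> list[str]:
    """Return the subsequence of ``tokens`` surviving the active filter.

    The result may be empty; callers that cannot embed an empty sentence
    are expected to fall back to the unfiltered tokens.
    """
    tokens = list(tokens)
    if spec.kind == "none":
        return tokens
    if spec.kind == "min_length":
        return [t for t in tokens if len(t) >= spec.min_letters]
    if spec.kind == "stopword":
        return [t for t in tokens if t not in spec.stopword_list]
    if corpus_counts is None:
        raise ValueError("frequency filter requires corpus_counts")
    return [t for t in tokens if corpus_counts.get(t, 0) < spec.max_occurrence]


@dataclass
class EmbeddingMatrix:
    """Row-aligned ids and vectors produced by one embedding configuration."""

    ids: list[str]
    X: np.ndarray
    backend_name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("vectors must be 2-D with one row per id")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("row ids must be unique")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, item_id: str) -> np.ndarray:
        return self.X[self.ids.index(item_id)]

    def subset(self, wanted: Sequence[str]) -> "EmbeddingMatrix":
        index = {i: r for r, i in enumerate(self.ids)}
        rows = [index[w] for w in wanted]
        return EmbeddingMatrix(list(wanted), self.X[rows], self.backend_name)

    def save(self, path: str | Path) -> None:
        """Write a portable text layout: one row per line, id then floats."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"# backend={self.backend_name} dim={self.dim}\n")
            for i, row in zip(self.ids, self.X):
                fh.write(i + "\t" + " ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        ids, rows = [], []
        backend = ""
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    for part in line[1:].split():
                        if part.startswith("backend="):
                            backend = part.removeprefix("backend=")
                    continue
                ident, vals = line.rstrip("\n").split("\t")
                ids.append(ident)
                rows.append([float(v) for v in vals.split()])
        return cls(ids, np.array(rows), backend)


class EmbedderBackend(Protocol):
    name: str
    dim: int
    deterministic: bool

    def encode(self, sentences: Sequence[str]) -> np.ndarray: ...


class HashingBackend:
    """Deterministic character-n-gram feature-hashing sentence encoder.

    Character 3–5-grams (within word boundaries) of the whitespace-joined
    filtered tokens are hashed into ``dim`` buckets with alternating signs
    and the resulting vector is L2-normalized.  Sentences with overlapping
    vocabulary therefore receive nearby vectors, with no trained weights
    and no randomness.
    """

    def __init__(self, dim: int = 768, ngram_range: tuple[int, int] = (3, 5)):
        self.name = f"hash-{dim}"
        self.dim = dim
        self.deterministic = True
        self._vectorizer = HashingVectorizer(
            analyzer="char_wb",
            ngram_range=ngram_range,
            n_features=dim,
            norm="l2",
            alternate_sign=True,
        )

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        if len(sentences) == 0:
            return np.empty((0, self.dim))
        return np.asarray(self._vectorizer.transform(list(sentences)).todense())


class TransformerBackend:
    """Sentence-transformer encoder (optional dependency)."""

    def __init__(self, model_name: str = "all-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "sentence-transformers is not installed; install the "
                "'transformer' extra or use the deterministic hashing "
                "backend (HashingBackend / --backend hash)"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.name = f"sbert-{model_name}"
        self.dim = self._model.get_sentence_embedding_dimension()
        self.deterministic = True

    def encode(self, sentences: Sequence[str]) -> np.ndarray:  # pragma: no cover
        return np.asarray(self._model.encode(list(sentences)))


def get_backend(name: str, dim: int = 768) -> EmbedderBackend:
    if name in ("hash", "hashing"):
        return HashingBackend(dim=dim)
    if name in ("transformer", "sbert"):
        return TransformerBackend()
    raise ValueError(f"unknown backend {name!r}; expected 'hash' or 'transformer'")


def _filtered_sentence(
    tokens: Sequence[str], spec: WordFilterSpec, counts: Counter | None
) -> str:
    kept = apply_word_filter(tokens, spec, counts)
    if not kept:  # fall back to the raw sentence rather than a zero vector
        kept = list(tokens)
    return " ".join(kept)


def embed_sentences(
    items: Sequence[Item],
    backend: EmbedderBackend,
    word_filter: WordFilterSpec = WordFilterSpec(),
    corpus_counts: Counter | None = None,
) -> EmbeddingMatrix:
    """Embed cleaned items: one row per item, ``dim`` = backend dimension.

    Identical filtered token sequences map to identical rows.  For the
    frequency filter, ``corpus_counts`` defaults to counts over ``items``.
    """
    if word_filter.kind == "frequency" and corpus_counts is None:
        corpus_counts = corpus_word_counts(items)
    sentences = [_filtered_sentence(it.tokens, word_filter, corpus_counts) for it in items]
    X = backend.encode(sentences)
    return EmbeddingMatrix([it.id for it in items], X, backend.name)


@dataclass
class ReductionModel:
    """Fitted PCA projection shared by items and anchor terms."""

    target_dim: int
    pca: PCA = field(repr=False)

    @property
    def component_matrix(self) -> np.ndarray:
        return self.pca.components_

    @property
    def explained_variance(self) -> np.ndarray:
        return self.pca.explained_variance_

    def transform(self, matrix: EmbeddingMatrix) -> EmbeddingMatrix:
        if len(matrix) == 0:
            return EmbeddingMatrix([], np.empty((0, self.target_dim)), matrix.backend_name)
        return EmbeddingMatrix(matrix.ids, self.pca.transform(matrix.X), matrix.backend_name)


def fit_reduce(
    matrix: EmbeddingMatrix, target_dim: int, seed: int = 0
) -> tuple[ReductionModel, EmbeddingMatrix]:
    """Fit a PCA of rank ``target_dim`` and return it with the reduced matrix."""
    if target_dim < 1 or target_dim > min(matrix.dim, len(matrix)):
        raise ValueError(
            f"target_dim={target_dim} must be in [1, min(dim={matrix.dim}, n={len(matrix)})]"
        )
    pca = PCA(n_components=target_dim, svd_solver="full", random_state=seed)
    reduced = pca.fit_transform(matrix.X)
    model = ReductionModel(target_dim=target_dim, pca=pca)
    return model, EmbeddingMatrix(matrix.ids, reduced, matrix.backend_name)


def embed_anchor_terms(
    terms: Sequence[str],
    backend: EmbedderBackend,
    word_filter: WordFilterSpec,
    reduction: ReductionModel,
    corpus_counts: Counter | None = None,
) -> EmbeddingMatrix:
    """Push ontology anchor phrases through the item pipeline (same filter,
    backend and fitted reduction) so anchors and items share one space."""
    anchors = [
        Item(id=f"anchor{j:03d}", source_measure="ontology", raw_text=t,
             normalized_text=t.lower(), tokens=tuple(t.lower().split()))
        for j, t in enumerate(terms)
    ]
    if not anchors:
        return EmbeddingMatrix([], np.empty((0, reduction.target_dim)), backend.name)
    base = embed_sentences(anchors, backend, word_filter, corpus_counts)
    return reduction.transform(base)
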