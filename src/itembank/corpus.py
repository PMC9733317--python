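"""Loading and cleaning of outcome-measure item corpora.

An *item* is one sentence-level question or task drawn from an outcome
measure (e.g. ``"able to climb stairs"``).  Corpora assembled from many
published measures arrive messy: exact duplicate rows, near-duplicate
"parallel" items, one-word fragments, UK/US spelling variants and
unexpanded acronyms.  This module normalizes item text, removes
duplicates, short items and expert-flagged items, and keeps an auditable
account of every removal so the final corpus size is reproducible
bookkeeping, not folklore.

Normalization applies, in order: lowercasing, number-sign stripping,
dash-to-underscore replacement, punctuation removal, acronym expansion
and spelling canonicalization (both dictionary-driven), and whitespace
collapsing.  The operation is idempotent.
"""

from __future__ import annotations

import csv
import re
import string
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Item",
    "CleaningReport",
    "Corpus",
    "NormalizationDictionaries",
    "CorpusFormatError",
    "load_corpus",
    "normalize_item",
    "normalize_corpus",
    "deduplicate",
    "filter_short_items",
    "apply_expert_flags",
    "cleaning_report",
    "clean_corpus",
]


class CorpusFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class Item:
    """One measurement sentence with provenance and normalization state."""

    id: str
    source_measure: str
    raw_text: str
    normalized_text: str = ""
    tokens: tuple[str, ...] = ()
    flags: frozenset[str] = frozenset()
    domain: str | None = None

    def with_flag(self, flag: str) -> "Item":
        return replace(self, flags=self.flags | {flag})


@dataclass
class CleaningReport:
    """Removal bookkeeping; ``n_output`` must balance against the inputs."""

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_expert_flag_removed: int = 0
    n_short_removed: int = 0
    n_output: int = 0

    def balances(self) -> bool:
        return (
            self.n_output
            == self.n_input
            - self.n_duplicates_removed
            - self.n_expert_flag_removed
            - self.n_short_removed
        ) and min(
            self.n_input,
            self.n_duplicates_removed,
            self.n_expert_flag_removed,
            self.n_short_removed,
            self.n_output,
        ) >= 0

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_expert_flag_removed": self.n_expert_flag_removed,
            "n_short_removed": self.n_short_removed,
            "n_output": self.n_output,
        }


@dataclass
class Corpus:
    """A collection of items plus the audit trail of cleaning removals."""

    items: list[Item]
    audit: CleaningReport = field(default_factory=CleaningReport)

    def __len__(self) -> int:
        return len(self.items)

    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [it.id for it in self.items],
                "measure": [it.source_measure for it in self.items],
                "domain": [it.domain for it in self.items],
                "item_text": [it.raw_text for it in self.items],
                "normalized_text": [it.normalized_text for it in self.items],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class NormalizationDictionaries:
    """Spelling (variant -> canonical) and acronym (short -> expansion) maps.

    Lookups are case-insensitive; keys are stored lowercased.  The default
    dictionaries ship as editable CSV resources with the package.
    """

    spelling_map: dict[str, str]
    abbreviation_map: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spelling_map", {k.lower(): v.lower() for k, v in self.spelling_map.items()}
        )
        object.__setattr__(
            self,
            "abbreviation_map",
            {k.lower(): v.lower() for k, v in self.abbreviation_map.items()},
        )

    @classmethod
    def default(cls) -> "NormalizationDictionaries":
        res = _ilres.files("itembank") / "resources"
        return cls(
            spelling_map=_read_two_column_csv(res / "spelling.csv"),
            abbreviation_map=_read_two_column_csv(res / "abbreviations.csv"),
        )

    @classmethod
    def empty(cls) -> "NormalizationDictionaries":
        return cls({}, {})


def _read_two_column_csv(path) -> dict[str, str]:
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return {row[0]: row[1] for row in reader if row}


def load_corpus(path: str | Path, *, id_prefix: str = "i") -> Corpus:
    """Read a corpus CSV with columns ``measure``, ``item_text`` (and
    optionally ``domain``) into a :class:`Corpus` with one item per row.

    Raw text is preserved verbatim; ``audit.n_input`` is set to the row
    count.  Missing required columns or an empty file raise
    :class:`CorpusFormatError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CorpusFormatError(f"{path} is empty") from exc
    for col in ("measure", "item_text"):
        if col not in frame.columns:
            raise CorpusFormatError(f"{path} lacks required column '{col}'")
    if len(frame) == 0:
        raise CorpusFormatError(f"{path} contains a header but no items")
    has_domain = "domain" in frame.columns
    has_ids = "id" in frame.columns
    if has_ids and frame["id"].duplicated().any():
        raise CorpusFormatError(f"{path} has duplicate values in the id column")
    width = max(4, len(str(len(frame))))
    items = [
        Item(
            id=str(row["id"]) if has_ids else f"{id_prefix}{idx:0{width}d}",
            source_measure=row["measure"],
            raw_text=row["item_text"],
            domain=(row["domain"] or None) if has_domain else None,
        )
        for idx, row in enumerate(frame.to_dict("records"))
    ]
    return Corpus(items=items, audit=CleaningReport(n_input=len(items)))


_DASHES = re.compile(r"[-‐‑‒–—]")
_NON_WORD = re.compile(r"[^a-z0-9_\s]+")
_WS = re.compile(r"\s+")
_PUNCT_EDGE = string.punctuation.replace("_", "")


def _scrub(text: str) -> str:
    """Character-level cleanup: number signs out, dashes to underscores,
    punctuation and non-printing characters stripped, whitespace collapsed."""
    text = text.lower().replace("#", " ")
    text = _DASHES.sub("_", text)
    text = _NON_WORD.sub(" ", text)
    return _WS.sub(" ", text).strip()


def normalize_text(raw: str, dicts: NormalizationDictionaries) -> str:
    tokens: list[str] = []
    for tok in _scrub(raw).split():
        if tok in dicts.abbreviation_map:
            tokens.extend(_scrub(dicts.abbreviation_map[tok]).split())
        else:
            tokens.append(tok)
    return " ".join(dicts.spelling_map.get(t, t) for t in tokens)


def normalize_item(item: Item, dicts: NormalizationDictionaries | None = None) -> Item:
    """Normalize one item's raw text.  Items whose text normalizes to the
    empty string are flagged ``short`` rather than dropped."""
    if not item.raw_text:
        raise ValueError(f"item {item.id} has empty raw_text")
    dicts = dicts if dicts is not None else NormalizationDictionaries.default()
    norm = normalize_text(item.raw_text, dicts)
    out = replace(item, normalized_text=norm, tokens=tuple(norm.split()))
    if not norm:
        out = out.with_flag("short")
    return out


def normalize_corpus(corpus: Corpus, dicts: NormalizationDictionaries | None = None) -> Corpus:
    dicts = dicts if dicts is not None else NormalizationDictionaries.default()
    return Corpus(items=[normalize_item(it, dicts) for it in corpus.items], audit=corpus.audit)


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep exactly one item per distinct normalized text (first occurrence
    wins, survivor order preserves input order)."""
    seen: set[str] = set()
    kept: list[Item] = []
    removed = 0
    for it in corpus.items:
        if not it.normalized_text and not it.tokens and "short" not in it.flags:
            raise ValueError("deduplicate requires a normalized corpus")
        if it.normalized_text in seen:
            removed += 1
        else:
            seen.add(it.normalized_text)
            kept.append(it)
    audit = replace(corpus.audit)
    audit.n_duplicates_removed += removed
    return Corpus(items=kept, audit=audit)


def filter_short_items(corpus: Corpus, min_words: int = 2) -> Corpus:
    """Drop items with fewer than ``min_words`` tokens, counting removals."""
    if min_words < 1:
        raise ValueError(f"min_words must be >= 1, got {min_words}")
    kept = [it for it in corpus.items if len(it.tokens) >= min_words]
    audit = replace(corpus.audit)
    audit.n_short_removed += len(corpus.items) - len(kept)
    return Corpus(items=kept, audit=audit)


def apply_expert_flags(corpus: Corpus, flagged_ids: Iterable[str]) -> Corpus:
    """Remove items an expert flagged as ambiguous, vague or parallel."""
    flagged = set(flagged_ids)
    known = set(corpus.ids())
    unknown = flagged - known
    if unknown:
        raise KeyError(f"flagged ids not in corpus: {sorted(unknown)}")
    kept = [it for it in corpus.items if it.id not in flagged]
    audit = replace(corpus.audit)
    audit.n_expert_flag_removed += len(corpus.items) - len(kept)
    return Corpus(items=kept, audit=audit)


def cleaning_report(corpus: Corpus) -> CleaningReport:
    corpus.audit.n_output = len(corpus.items)
    if not corpus.audit.balances():
        raise AssertionError(f"cleaning report does not balance: {corpus.audit}")
    return corpus.audit


def clean_corpus(
    corpus: Corpus,
    dicts: NormalizationDictionaries | None = None,
    flagged_ids: Sequence[str] = (),
    min_words: int = 2,
) -> Corpus:
    """Full cleaning pipeline: normalize, deduplicate, remove expert-flagged
    items, drop short items, and finalize the audit report.

    Deduplication runs after normalization so that case, spelling and
    abbreviation variants of the same sentence collapse to one row.
    """
    corpus = normalize_corpus(corpus, dicts)
    corpus = deduplicate(corpus)
    surviving_flags = [fid for fid in flagged_ids if fid in set(corpus.ids())]
    corpus = apply_expert_flags(corpus, surviving_flags)
    corpus = filter_short_items(corpus, min_words=min_words)
    cleaning_report(corpus)
    return corpus
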