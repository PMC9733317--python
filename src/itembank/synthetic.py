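"""Synthetic item corpora with planted domain structure.

The real corpora this pipeline targets — thousands of sentence-level
items pooled from hundreds of published outcome measures — are not
freely redistributable, so every stage is exercised against generated
corpora that plant a known domain partition and inject the pathologies
such corpora exhibit: exact duplicate rows, near-duplicate "parallel"
items, sub-2-word fragments, UK spellings and unexpanded acronyms.

Items are short template sentences over per-domain core vocabularies
(disjoint sets of synthetic words) mixed with a shared noise vocabulary
at a configurable rate.  This is deliberately not natural English: a
lexical embedding backend only needs vocabulary overlap to carry the
domain signal, and synthetic vocabularies make ground truth exact.

A :class:`SimulatedOracle` stands in for the expert panel, answering
pair ("same domain?") and label queries from the planted truth with an
independent error rate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    CleaningReport,
    Corpus,
    Item,
    NormalizationDictionaries,
    normalize_text,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SimulatedOracle",
    "generate_corpus",
    "generate_anchor_terms",
    "make_oracle",
    "paper_scale_spec",
]

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"



@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic corpus.

    ``items_per_domain`` may be an int or an explicit per-domain sequence;
    ``total_base_items`` (if given) overrides it, spreading items as evenly
    as possible across domains.  Pathology counts are exact: the generator
    injects precisely ``n_duplicates`` exact copies, ``n_parallel``
    one-word-substitution near-duplicates and ``n_short`` one-word items.
    """

    n_domains: int = 24
    items_per_domain: int | Sequence[int] = 60
    total_base_items: int | None = None
    core_vocab_size: int = 10
    shared_noise_vocab_size: int = 120
    noise_word_rate: float = 0.2
    n_duplicates: int = 0
    n_parallel: int = 0
    n_short: int = 0
    uk_spelling_rate: float = 0.0
    abbreviation_rate: float = 0.0
    seed: int = 0

    def domain_sizes(self) -> list[int]:
        if self.total_base_items is not None:
            base, extra = divmod(self.total_base_items, self.n_domains)
            return [base + (1 if d < extra else 0) for d in range(self.n_domains)]
        if isinstance(self.items_per_domain, int):
            return [self.items_per_domain] * self.n_domains
        sizes = list(self.items_per_domain)
        if len(sizes) != self.n_domains:
            raise ValueError("items_per_domain sequence must have n_domains entries")
        return sizes

    def validate(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if min(self.domain_sizes()) < 1:
            raise ValueError("every domain needs at least one item")
        for name in ("noise_word_rate", "uk_spelling_rate", "abbreviation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_duplicates", "n_parallel", "n_short"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_base = sum(self.domain_sizes())
        if self.n_duplicates + self.n_parallel > n_base:
            raise ValueError("cannot inject more duplicates/parallels than base items")


def paper_scale_spec(seed: int = 0) -> SyntheticSpec:
    """A corpus at the scale of a real pooled item corpus: 24 domains,
    1611 distinct usable items, plus 267 duplicates, 97 parallel items
    and 134 fragments (2109 rows in total)."""
    return SyntheticSpec(
        n_domains=24,
        total_base_items=1611,
        n_duplicates=267,
        n_parallel=97,
        n_short=134,
        uk_spelling_rate=0.05,
        abbreviation_rate=0.03,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted item->domain labels plus a registry of injected pathologies."""

    labels: dict[str, str]
    domain_vocab: dict[str, list[str]]
    duplicate_ids: list[str] = field(default_factory=list)
    parallel_ids: list[str] = field(default_factory=list)
    short_ids: list[str] = field(default_factory=list)

    @property
    def domains(self) -> list[str]:
        return sorted(self.domain_vocab)

    def labels_for(self, ids: Sequence[str]) -> dict[str, str]:
        return {i: self.labels[i] for i in ids if i in self.labels}


def _word_pool(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct pronounceable synthetic words (2-4 CV syllables)."""
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        syllables = rng.integers(2, 5)
        word = "".join(
            rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
            for _ in range(syllables)
        )
        if word not in seen:
            seen.add(word)
            pool.append(word)
    return pool


def _make_sentence(
    rng: np.random.Generator,
    core: list[str],
    noise: list[str],
    noise_rate: float,
) -> str:
    # Content words only, no carrier phrase: a shared English template would
    # add identical character mass to every item and wash out the
    # between-domain signal a lexical backend relies on.
    n_content = int(rng.integers(3, 9))
    words = [
        str(rng.choice(noise)) if rng.random() < noise_rate else str(rng.choice(core))
        for _ in range(n_content)
    ]
    return " ".join(words)


def generate_corpus(
    spec: SyntheticSpec,
    dicts: NormalizationDictionaries | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Generate a raw (uncleaned) corpus and its ground truth.

    Base items have distinct normalized texts by construction, so the
    cleaning pipeline removes exactly the injected pathology counts.
    Row order is shuffled; determinism follows from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dicts = dicts if dicts is not None else NormalizationDictionaries.default()
    uk_variants = list(dicts.spelling_map)
    acronyms = list(dicts.abbreviation_map)

    sizes = spec.domain_sizes()
    n_core = spec.n_domains * spec.core_vocab_size
    pool = _word_pool(rng, n_core + spec.shared_noise_vocab_size + spec.n_short + 8)
    domain_vocab = {
        f"domain{d:02d}": pool[d * spec.core_vocab_size : (d + 1) * spec.core_vocab_size]
        for d in range(spec.n_domains)
    }
    noise_vocab = pool[n_core : n_core + spec.shared_noise_vocab_size]
    short_words = pool[n_core + spec.shared_noise_vocab_size :]

    labels: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []  # (id, domain, raw_text)
    seen_norm: set[str] = set()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"s{counter:05d}"

    for domain, size in zip(sorted(domain_vocab), sizes):
        core = domain_vocab[domain]
        for _ in range(size):
            for _attempt in range(100):
                text = _make_sentence(rng, core, noise_vocab, spec.noise_word_rate)
                if rng.random() < spec.uk_spelling_rate and uk_variants:
                    text += " " + str(rng.choice(uk_variants))
                if rng.random() < spec.abbreviation_rate and acronyms:
                    text += " " + str(rng.choice(acronyms)).upper()
                norm = normalize_text(text, dicts)
                if norm not in seen_norm:
                    break
            else:  # pragma: no cover - vocabulary exhausted
                raise RuntimeError("could not generate a distinct item; enlarge vocabulary")
            seen_norm.add(norm)
            iid = new_id()
            labels[iid] = domain
            rows.append((iid, domain, text))

    base_rows = list(rows)
    truth = GroundTruth(labels=labels, domain_vocab=domain_vocab)

    # exact duplicates: verbatim copies of random base rows
    for _ in range(spec.n_duplicates):
        src_id, domain, text = base_rows[rng.integers(len(base_rows))]
        iid = new_id()
        truth.duplicate_ids.append(iid)
        labels[iid] = domain
        rows.append((iid, domain, text))

    # parallel items: one content word substituted, still unique text
    for _ in range(spec.n_parallel):
        for _attempt in range(100):
            _, domain, text = base_rows[rng.integers(len(base_rows))]
            words = text.split()
            pos = int(rng.integers(2, len(words))) if len(words) > 2 else len(words) - 1
            words[pos] = str(rng.choice(noise_vocab))
            cand = " ".join(words)
            norm = normalize_text(cand, dicts)
            if norm not in seen_norm:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a distinct parallel item")
        seen_norm.add(norm)
        iid = new_id()
        truth.parallel_ids.append(iid)
        labels[iid] = domain
        rows.append((iid, domain, cand))

    # fragments with fewer than two words
    for j in range(spec.n_short):
        iid = new_id()
        truth.short_ids.append(iid)
        rows.append((iid, "", short_words[j % len(short_words)] + str(j)))

    order = rng.permutation(len(rows))
    items = [
        Item(
            id=rows[r][0],
            source_measure=f"measure{int(rows[r][0][1:]) % 40:02d}",
            raw_text=rows[r][2],
            domain=rows[r][1] or None,
        )
        for r in order
    ]
    corpus = Corpus(items=items, audit=CleaningReport(n_input=len(items)))
    return corpus, truth


def generate_anchor_terms(
    truth: GroundTruth, per_domain: int = 1, seed: int = 0
) -> list[str]:
    """Short anchor phrases (two core words) per planted domain, emulating
    ontology category names that name the domain's subject matter."""
    if per_domain < 1:
        raise ValueError("per_domain must be >= 1")
    rng = np.random.default_rng(seed)
    terms = []
    for domain in truth.domains:
        vocab = truth.domain_vocab[domain]
        for _ in range(per_domain):
            pair = rng.choice(vocab, size=2, replace=False)
            terms.append(f"{pair[0]} {pair[1]}")
    return terms


def _stable_uniform(seed: int, *parts: str) -> float:
    """Deterministic, call-order-independent uniform draw in [0, 1)."""
    digest = hashlib.sha256(("|".join((str(seed),) + parts)).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


@dataclass
class SimulatedOracle:
    """Expert stand-in answering pair and label queries from planted truth.

    Each answer is flipped independently with probability ``error_rate``;
    the flip is a deterministic function of (seed, query), so repeated and
    reordered queries get identical answers.
    """

    truth: GroundTruth
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    def same_domain(self, item_a: str, item_b: str) -> bool:
        a, b = sorted((item_a, item_b))
        true_answer = self.truth.labels[a] == self.truth.labels[b]
        flip = _stable_uniform(self.seed, "pair", a, b) < self.error_rate
        return true_answer != flip

    def label(self, item_id: str) -> str:
        true_label = self.truth.labels[item_id]
        if _stable_uniform(self.seed, "label", item_id) >= self.error_rate:
            return true_label
        others = [d for d in self.truth.domains if d != true_label]
        if not others:
            return true_label
        idx = int(_stable_uniform(self.seed, "label-alt", item_id) * len(others))
        return others[min(idx, len(others) - 1)]


def make_oracle(truth: GroundTruth, error_rate: float = 0.0, seed: int = 0) -> SimulatedOracle:
    return SimulatedOracle(truth=truth, error_rate=error_rate, seed=seed)
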