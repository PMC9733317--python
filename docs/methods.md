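# Methods

`itembank` implements a pipeline for condensing a corpus of sentence-level
outcome-measure items (e.g. "able to climb stairs", pooled from hundreds of
published instruments) into a small set of named, defined outcome domains
with their item banks. The pipeline has five stages: corpus cleaning,
sentence embedding, ontology-anchored weighted k-means with grid-search
model selection, an iterative expert-in-the-loop refinement protocol, and a
final curation pass with full bookkeeping. This note records the models,
the defaults and why, the numerical choices, and what the synthetic test
corpora do and do not establish.

## Corpus cleaning

Items arrive as CSV rows (`measure, domain, item_text`). Normalization
lowercases, strips number signs and punctuation, replaces dashes with
underscores, expands acronyms (`6mwt` → `six-minute walking test`) and
canonicalizes UK spellings (`behaviour` → `behavior`) from editable CSV
dictionaries shipped with the package; unknown acronyms pass through
unchanged. The operation is idempotent, and text that normalizes to the
empty string is flagged rather than silently dropped.

Cleaning order is **normalize → deduplicate → expert flags → short filter**.
The ordering is a package decision: deduplication must see normalized text
so that case, spelling and abbreviation variants of one sentence collapse,
and expert flags are resolved before the short filter so each removal is
attributed to exactly one rule. A duplicate is an *exact* match of
normalized text (spreadsheet-unique semantics); near-duplicate "parallel"
items are an expert judgment, supplied as a flag list, not automated.
Spelled-out number conversion is not attempted. The audit report enforces

    n_output = n_input − duplicates − expert_flagged − short

for every run, with short meaning fewer than 2 words (configurable).

## Embedding

Tokens pass a word filter — none, minimum word length (default 4 letters),
stop-words (scikit-learn's English list), or corpus frequency (drop words
occurring ≥ 20 times) — and the filtered sentence is encoded by a pluggable
backend. The default backend hashes character 3–5-grams (within word
boundaries) into 768 dimensions with alternating signs and L2-normalizes;
it is deterministic, download-free, and places sentences with shared
vocabulary near each other, which is the property every later stage uses.
A sentence-transformer backend satisfies the same interface where the
optional dependency is installed. Sentences emptied by a filter fall back
to their unfiltered tokens rather than embedding to zero.

PCA reduces the 768-dim vectors to a working dimension (grid default
{5, 10, 25, 50}); distance-based clustering is unreliable in hundreds of
dimensions. The PCA is fitted on the **union** of item and anchor vectors
so both populations share one reduced space, and anchors always travel
through the identical filter/backend/reduction as the items.

## Anchored clustering and model selection

Ontology anchor terms (category names, e.g. ICF categories when clustering
mobility items) join k-means as weighted pseudo-points. With `n` items and
`m` anchors at anchor weight `w`, each item has weight 1 and each anchor
weight `w·n/m`: the anchor population carries total mass `w` relative to
the data, so `w = 0.5` means the ontology counts half as much as the
corpus, and `w = 0` reproduces item-only k-means bit-for-bit. k-means uses
k-means++ initialization, 10 restarts keeping the lowest weighted inertia,
tolerance 1e-6, at most 300 Lloyd iterations, and an explicit seed.

Clustering quality is the mean silhouette over **items only** (Euclidean
distance); anchors are guides, not observations, so they are excluded from
every quality score. The grid search crosses k (default 4–40), the four
word filters, the PCA dimensions and the anchor weights, scores every
combination, and retains the 10 best by the active heuristic; ties prefer
smaller k (parsimony), then a fixed lexicographic parameter order. The
short-list exists because the heuristic alone is not trusted: a human (or
the `select` override hook) picks among the retained clusterings.

## The iterative expert loop

Round 1 clusters the untouched space with the silhouette heuristic — no
annotation-based score exists yet. After selection, the items nearest each
centroid (default 30 per cluster, mirroring expert panels that review the
top of each cluster) are sampled into pair queries — within- and
cross-cluster, default 5 + 5 per cluster — answered by the annotation
source: a human file, or the simulated oracle.

Rounds 2 and 3 first refine the embedding space from the accumulated
constraints, then repeat the grid search with annotation-based heuristics:
pair accuracy in round 2, the mean of pair accuracy and macro label F1 in
round 3. Labels are collected on the round-2 selection; round 3 trains on
pair relations **plus** label-derived relations, and annotations are never
discarded between rounds. Each round's selected clustering is reported
with E1 (binary F1 on the annotated pairs) and E2 (macro label F1).

Refinement is desk-scale metric learning rather than encoder fine-tuning:
a linear map `W` over the frozen 768-dim backend space, initialized at the
identity, minimizing

    L(W) = mean_ML ‖W d‖² + mean_CL max(0, margin − ‖W d‖)²

by full-batch gradient descent (margin 1.0 on the unit-norm embedding
scale, rate 0.5, 60 epochs). The step is halved whenever it would increase
the loss, so the epoch-loss sequence is non-increasing by construction.
Round 3 learns its map on the round-2-transformed space, so refinements
compose. The refiner sits behind a small interface (fit → transform →
apply), so a genuine encoder fine-tuner can be substituted without
touching the protocol.

## Curation

After the final round, items with per-item silhouette below `tau`
(default 0 — nearer, on average, to another cluster than their own) are
outliers. Expert directives (`move_item`, `new_cluster`, `remove_cluster`,
`rename_cluster`) apply first; remaining outliers move to the nearest
*other* centroid. Item count is conserved. The ledger records, per
cluster, initial size, outliers removed, items reassigned in, and final
size; rows satisfy `final = initial − removed + reassigned_in` exactly
(construction guarantees it; the container re-checks), clusters drained to
zero are *removed*, clusters born from reassigned items are *new*, and
rows are ordered by descending final size. The implementation refuses to
produce non-conserving totals: sum of final sizes always equals sum of
initial sizes when no items are deleted. The outcome-set artifact (JSON +
CSV) lists each named cluster with a definition (an editable resource —
definitions are authored, not computed) and its member items.

## Synthetic corpora and the simulated oracle

The generator plants a known domain partition: each domain owns a disjoint
core vocabulary of synthetic CV-syllable words (default 10 per domain),
items are 3–8 content words drawn uniformly from the domain's core
vocabulary, with each word independently replaced by a shared noise-pool
word at `noise_word_rate`. Pathologies are injected in exact counts —
verbatim duplicate rows, "parallel" items (one-word substitutions of an
existing item), one-word fragments — plus UK-spelling and acronym
insertions at configurable rates. Base items are guaranteed distinct
after normalization, so the cleaning pipeline removes *exactly* the
injected counts. The full-scale recipe (24 domains, 1611 base items, 267
duplicates, 97 parallels, 134 fragments — 2109 rows) mirrors the scale of
a real pooled mobility-item corpus.

Two generator choices matter and were made deliberately. Items carry no
shared English carrier phrase ("ability to …"): a constant prefix adds
identical character mass to every item under the hashing backend, washing
out between-domain signal and displacing anchors, which are bare category
phrases. And core vocabularies are small (10 words) so same-domain items
reliably share vocabulary — the synthetic analogue of real item banks
repeating a domain's key terms. Anchor terms are two core words of their
domain.

The simulated oracle answers pair and label queries from the planted
truth, flipping each answer independently with probability `error_rate`;
flips are a deterministic hash of (seed, query), so answers are stable
across repeats and argument order. Label errors draw a uniformly random
wrong domain.

What the synthetic corpora do **not** emulate: natural English syntax and
synonymy (two real items can share a domain with zero common words — only
a trained encoder captures that), domain overlap and hierarchy, length and
style heterogeneity across instruments, and annotator biases that are not
independent coin flips. Passing tests therefore establish that the
machinery — bookkeeping, weighting, selection, constraint learning,
curation arithmetic — behaves as specified, not that the hashing backend
would recover domains from real clinical text; on real corpora the
transformer backend is the intended encoder.

## Problem sizes and numerical conventions

End-to-end checks run 24 domains × 60 items at noise 0.2 with a 5%-error
oracle over a reduced grid (k 20–28, dims {10, 25}, weights {0, 0.25}) for
recovery, and noise 0 with k 16–32, dim 25, weight 0.25 for model
selection, five replicate seeds each — sizes chosen so a replicate
finishes in seconds on one CPU while preserving the full-scale corpus
shape. Ties in majority-label mapping break to the lexicographically
smallest label; pair F1 returns 0 when nothing is co-clustered; silhouette
raises on a single cluster rather than returning a sentinel; empty k-means
clusters are re-seeded by scikit-learn's relocation policy (the highest-
inertia points). All randomness flows from explicit integer seeds;
repeated runs are bit-identical.

## Known limitations

- The hashing backend is lexical: it cannot merge synonymous items with
  disjoint vocabulary. It is the deterministic test backend, not a claim
  about real-text performance.
- Linear metric refinement cannot reshape the space as flexibly as encoder
  fine-tuning; with many contradictory constraints it plateaus.
- Grid search cost is linear in grid size; the full 2368-point default
  grid at corpus scale is minutes, not seconds.
- Outlier detection inherits silhouette's bias toward convex, comparable-
  density clusters.
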