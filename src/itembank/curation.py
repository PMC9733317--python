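"""Post-clustering expert curation and the final outcome set.

After the last clustering round, items that sit poorly in their cluster
(per-item silhouette below a threshold) are flagged as outliers and
reassigned — by explicit expert directive where one exists, otherwise
to the nearest other centroid.  Experts may also create clusters from
outliers, dissolve clusters entirely, or rename them.  Every movement
is tracked in a per-cluster ledger (initial size, outliers removed,
items reassigned in, final size), whose rows balance exactly:

    final = initial - removed + reassigned_in

Clusters that lose all items are *removed*; clusters born from
reassigned items are *new*.  The surviving named clusters, with their
definitions and member items, form the outcome set artifact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import AnchoredKMeansResults, silhouette_samples
from .embedding import EmbeddingMatrix

__all__ = [
    "Directive",
    "CurationLedger",
    "OutcomeSet",
    "CuratedClustering",
    "detect_outliers",
    "reassign_items",
    "build_ledger",
    "emit_outcome_set",
    "load_outcome_set",
]


@dataclass(frozen=True)
class Directive:
    """One expert curation instruction.

    kinds: ``move_item`` (item_id, to_cluster), ``new_cluster`` (name,
    item_ids), ``remove_cluster`` (cluster), ``rename_cluster`` (cluster,
    name).
    """

    kind: str
    item_id: str | None = None
    item_ids: tuple[str, ...] = ()
    cluster: int | None = None
    to_cluster: int | None = None
    name: str | None = None

    _KINDS = ("move_item", "new_cluster", "remove_cluster", "rename_cluster")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown directive kind {self.kind!r}")


@dataclass
class CuratedClustering:
    """Assignments after curation, plus cluster display names."""

    assignments: dict[str, int]
    names: dict[int, str] = field(default_factory=dict)
    centroids: np.ndarray | None = None

    def clusters(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.assignments.items() if c == cluster]


def _assignments_of(clustering) -> dict[str, int]:
    if isinstance(clustering, AnchoredKMeansResults):
        return dict(clustering.assignments)
    if isinstance(clustering, CuratedClustering):
        return dict(clustering.assignments)
    return dict(clustering)


def detect_outliers(
    clustering,
    embeddings: EmbeddingMatrix,
    tau: float = 0.0,
) -> dict[int, list[str]]:
    """Items whose per-item silhouette falls below ``tau``, by cluster.

    ``tau = 0`` flags items nearer (on average) to another cluster than
    to their own — the natural "does not fit well enough" reading.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [-1, 1], got {tau}")
    assignments = _assignments_of(clustering)
    scores = silhouette_samples(embeddings, assignments)
    out: dict[int, list[str]] = {}
    for item_id, s in scores.items():
        if s < tau:
            out.setdefault(assignments[item_id], []).append(item_id)
    return {c: sorted(ids) for c, ids in sorted(out.items())}


def _flatten(outliers: dict[int, list[str]] | Sequence[str]) -> list[str]:
    if isinstance(outliers, dict):
        return [i for ids in outliers.values() for i in ids]
    return list(outliers)


def reassign_items(
    clustering,
    outliers: dict[int, list[str]] | Sequence[str],
    directives: Sequence[Directive] = (),
    embeddings: EmbeddingMatrix | None = None,
) -> CuratedClustering:
    """Apply expert directives, then move remaining outliers to the nearest
    other centroid.  Item count is conserved; clusters may appear
    (``new_cluster``) or empty out (``remove_cluster`` or full outlier
    drain)."""
    if isinstance(clustering, AnchoredKMeansResults):
        assignments = dict(clustering.assignments)
        centroids = clustering.centroids
        names: dict[int, str] = {}
    else:
        assignments = dict(clustering.assignments)
        centroids = clustering.centroids
        names = dict(clustering.names)
    flat_outliers = [i for i in _flatten(outliers)]
    unknown = [i for i in flat_outliers if i not in assignments]
    if unknown:
        raise KeyError(f"outlier ids not in clustering: {unknown}")

    existing = set(assignments.values())
    next_cluster = max(existing) + 1 if existing else 0
    pending = set(flat_outliers)

    for d in directives:
        if d.kind == "rename_cluster":
            if d.cluster not in existing:
                raise KeyError(f"rename_cluster: unknown cluster {d.cluster}")
            names[d.cluster] = d.name or names.get(d.cluster, "")
        elif d.kind == "move_item":
            if d.item_id not in assignments:
                raise KeyError(f"move_item: unknown item {d.item_id!r}")
            if d.to_cluster not in existing:
                raise KeyError(
                    f"move_item: cluster {d.to_cluster} does not exist "
                    "(use new_cluster to create one)"
                )
            assignments[d.item_id] = d.to_cluster
            pending.discard(d.item_id)
        elif d.kind == "new_cluster":
            members = d.item_ids
            missing = [i for i in members if i not in assignments]
            if missing:
                raise KeyError(f"new_cluster: unknown items {missing}")
            cid = next_cluster
            next_cluster += 1
            existing.add(cid)
            if d.name:
                names[cid] = d.name
            for i in members:
                assignments[i] = cid
                pending.discard(i)
        elif d.kind == "remove_cluster":
            if d.cluster not in existing:
                raise KeyError(f"remove_cluster: unknown cluster {d.cluster}")
            pending.update(i for i, c in assignments.items() if c == d.cluster)
            existing.discard(d.cluster)

    if pending:
        if embeddings is None or centroids is None:
            raise ValueError(
                "auto-reassignment of outliers requires embeddings and centroids"
            )
        for item_id in sorted(pending):
            own = assignments[item_id]
            x = embeddings.row(item_id)
            candidates = [c for c in sorted(existing) if c != own and c < len(centroids)]
            if not candidates:
                raise ValueError(f"no candidate cluster to absorb {item_id!r}")
            dists = [float(np.linalg.norm(x - centroids[c])) for c in candidates]
            assignments[item_id] = candidates[int(np.argmin(dists))]

    return CuratedClustering(assignments=assignments, names=names, centroids=centroids)


@dataclass
class CurationLedger:
    """Per-cluster bookkeeping of the curation pass."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.frame[
            self.frame["final_size"]
            != self.frame["initial_size"]
            - self.frame["outliers_removed"]
            + self.frame["reassigned_in"]
        ]
        if len(bad):
            raise AssertionError(f"ledger rows do not balance:\n{bad}")

    def row(self, name: str) -> pd.Series:
        return self.frame.set_index("name").loc[name]

    def to_table(self) -> pd.DataFrame:
        """Display table with removal/reassignment percentages."""
        f = self.frame

        def pct(numer: int, denom: int) -> str:
            return f"{numer} ({round(100 * numer / denom) if denom else 0})"

        suffix = {"new": " (New)", "removed": " (Removed)", "kept": ""}
        return pd.DataFrame(
            {
                "Name": [n + suffix[s] for n, s in zip(f["name"], f["status"])],
                "Initial size": f["initial_size"],
                "Outliers removed (%)": [
                    pct(r, i) for r, i in zip(f["outliers_removed"], f["initial_size"])
                ],
                "Outliers reassigned (%)": [
                    pct(r, fi) for r, fi in zip(f["reassigned_in"], f["final_size"])
                ],
                "Final size": f["final_size"],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def build_ledger(
    before,
    after,
    names: Mapping[int, str] | None = None,
) -> CurationLedger:
    """Account for every cluster across a curation pass.

    ``before`` and ``after`` must cover the same item universe.  A row's
    ``outliers_removed`` counts items that left the cluster,
    ``reassigned_in`` items that arrived; statuses follow the bookkeeping
    convention (*removed* = fully drained, *new* = born from reassigned
    items).  Rows are ordered by descending final size.
    """
    b = _assignments_of(before)
    a = _assignments_of(after)
    if set(b) != set(a):
        only = set(b) ^ set(a)
        raise ValueError(f"clusterings cover different items (e.g. {sorted(only)[:5]})")
    names = dict(names or {})
    if isinstance(after, CuratedClustering):
        names = {**after.names, **names}
    clusters = sorted(set(b.values()) | set(a.values()))
    rows = []
    for c in clusters:
        initial = sum(1 for v in b.values() if v == c)
        final = sum(1 for v in a.values() if v == c)
        removed = sum(1 for i, v in b.items() if v == c and a[i] != c)
        arrived = sum(1 for i, v in a.items() if v == c and b[i] != c)
        if final == 0:
            status = "removed"
        elif initial == 0:
            status = "new"
        else:
            status = "kept"
        rows.append(
            {
                "cluster": c,
                "name": names.get(c, f"cluster {c}"),
                "initial_size": initial,
                "outliers_removed": removed,
                "reassigned_in": arrived,
                "final_size": final,
                "status": status,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["final_size", "initial_size"], ascending=[False, False], kind="stable"
    )
    return CurationLedger(frame=frame.reset_index(drop=True))


@dataclass
class OutcomeSet:
    """The deliverable: named, defined clusters with their member items."""

    clusters: list[dict]
    provenance: dict = field(default_factory=dict)

    def names(self) -> list[str]:
        return [c["name"] for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c["name"] for c in self.clusters],
                "definition": [c["definition"] for c in self.clusters],
                "n_items": [len(c["items"]) for c in self.clusters],
            }
        )


def emit_outcome_set(
    clustering,
    names: Mapping[int, str],
    definitions: Mapping[str, str] | None = None,
    path: str | Path | None = None,
    provenance: dict | None = None,
) -> OutcomeSet:
    """Assemble (and optionally write) the outcome set: clusters ordered by
    descending size, each with a name, definition and member item ids.

    Writes ``<path>.json`` and ``<path>.csv`` when ``path`` is given.
    Missing definitions produce a warning and an empty string; duplicate
    names are an error.
    """
    assignments = _assignments_of(clustering)
    definitions = dict(definitions or {})
    clusters = sorted(set(assignments.values()))
    unnamed = [c for c in clusters if c not in names]
    if unnamed:
        raise ValueError(f"every cluster needs a name; missing: {unnamed}")
    chosen = [names[c] for c in clusters]
    if len(set(chosen)) != len(chosen):
        dupes = sorted({n for n in chosen if chosen.count(n) > 1})
        raise ValueError(f"duplicate cluster names: {dupes}")
    entries = []
    for c in clusters:
        name = names[c]
        if name not in definitions:
            warnings.warn(f"no definition provided for cluster {name!r}", stacklevel=2)
        entries.append(
            {
                "name": name,
                "definition": definitions.get(name, ""),
                "items": sorted(i for i, v in assignments.items() if v == c),
            }
        )
    entries.sort(key=lambda e: (-len(e["items"]), e["name"]))
    outcome = OutcomeSet(clusters=entries, provenance=provenance or {})
    if path is not None:
        path = Path(path)
        with path.with_suffix(".json").open("w", encoding="utf-8") as fh:
            json.dump(
                {"clusters": outcome.clusters, "provenance": outcome.provenance},
                fh,
                indent=2,
            )
        outcome.to_frame().to_csv(path.with_suffix(".csv"), index=False)
    return outcome


def load_outcome_set(path: str | Path) -> OutcomeSet:
    with Path(path).with_suffix(".json").open(encoding="utf-8") as fh:
        payload = json.load(fh)
    return OutcomeSet(clusters=payload["clusters"], provenance=payload.get("provenance", {}))
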