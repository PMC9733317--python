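"""Outlier detection, reassignment, the curation ledger and the outcome set."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itembank.cluster import AnchoredKMeans
from itembank.curation import (
    CuratedClustering,
    Directive,
    build_ledger,
    detect_outliers,
    emit_outcome_set,
    load_outcome_set,
    reassign_items,
)
from itembank.embedding import EmbeddingMatrix


def matrix(X, prefix="p"):
    X = np.asarray(X, dtype=float)
    return EmbeddingMatrix([f"{prefix}{i}" for i in range(len(X))], X)


def planted_two_clusters(midpoint=False):
    """Two tight planted clusters; optionally an item exactly between them."""
    left = np.array([[0.0, 0.0], [0.2, 0.0], [0.0, 0.2], [0.2, 0.2]])
    right = left + np.array([10.0, 0.0])
    rows = [left, right]
    if midpoint:
        rows.append(np.array([[5.0, 0.1]]))
    X = np.vstack(rows)
    emb = matrix(X)
    assignments = {emb.ids[i]: int(i >= 4) for i in range(8)}
    if midpoint:
        assignments[emb.ids[8]] = 0
    centroids = np.vstack([left.mean(axis=0), right.mean(axis=0)])
    return emb, assignments, centroids


def per_item_silhouette_formula(X, labels, i):
    same = [j for j in range(len(X)) if j != i and labels[j] == labels[i]]
    a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
    b = min(
        np.mean([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if labels[j] == c])
        for c in set(labels)
        if c != labels[i]
    )
    return (b - a) / max(a, b)


class TestDetectOutliers:
    def test_clean_separation_flags_nothing(self):
        emb, assignments, _ = planted_two_clusters()
        assert detect_outliers(assignments, emb, tau=0.0) == {}

    def test_tau_one_flags_all_non_coincident_items(self):
        emb, assignments, _ = planted_two_clusters()
        flagged = detect_outliers(assignments, emb, tau=1.0)
        assert sorted(i for ids in flagged.values() for i in ids) == sorted(emb.ids)

    def test_midpoint_item_flagged_at_quarter_threshold(self):
        emb, assignments, _ = planted_two_clusters(midpoint=True)
        labels = np.array([assignments[i] for i in emb.ids])
        s_mid = per_item_silhouette_formula(emb.X, labels, 8)
        assert s_mid < 0.25  # oracle agrees the midpoint item fits poorly
        flagged = detect_outliers(assignments, emb, tau=0.25)
        assert emb.ids[8] in flagged.get(0, [])

    def test_tau_out_of_range_rejected(self):
        emb, assignments, _ = planted_two_clusters()
        with pytest.raises(ValueError):
            detect_outliers(assignments, emb, tau=1.5)


class TestReassign:
    def test_flagged_item_moves_to_nearest_other_centroid(self):
        emb, assignments, centroids = planted_two_clusters(midpoint=True)
        start = CuratedClustering(assignments=assignments, centroids=centroids)
        after = reassign_items(start, [emb.ids[8]], embeddings=emb)
        assert after.assignments[emb.ids[8]] == 1
        assert sorted(after.assignments) == sorted(assignments)

    def test_new_cluster_directive(self):
        emb, assignments, centroids = planted_two_clusters()
        start = CuratedClustering(assignments=assignments, centroids=centroids)
        members = tuple(emb.ids[:2])
        after = reassign_items(
            start,
            [],
            [Directive(kind="new_cluster", item_ids=members, name="fragments")],
        )
        clusters = set(after.assignments.values())
        assert len(clusters) == 3
        new_id = after.assignments[members[0]]
        assert after.names[new_id] == "fragments"
        assert len(after.assignments) == len(assignments)  # conservation

    def test_remove_cluster_drains_members_to_other_centroids(self):
        emb, assignments, centroids = planted_two_clusters()
        start = CuratedClustering(assignments=assignments, centroids=centroids)
        after = reassign_items(
            start, [], [Directive(kind="remove_cluster", cluster=0)], embeddings=emb
        )
        assert all(c == 1 for c in after.assignments.values())

    def test_move_to_nonexistent_cluster_errors(self):
        emb, assignments, centroids = planted_two_clusters()
        start = CuratedClustering(assignments=assignments, centroids=centroids)
        with pytest.raises(KeyError, match="new_cluster"):
            reassign_items(
                start,
                [],
                [Directive(kind="move_item", item_id=emb.ids[0], to_cluster=9)],
            )

    def test_item_count_conserved_under_directive_mix(self):
        emb, assignments, centroids = planted_two_clusters(midpoint=True)
        start = CuratedClustering(assignments=assignments, centroids=centroids)
        after = reassign_items(
            start,
            [emb.ids[8]],
            [
                Directive(kind="new_cluster", item_ids=(emb.ids[0],), name="solo"),
                Directive(kind="move_item", item_id=emb.ids[1], to_cluster=1),
            ],
            embeddings=emb,
        )
        assert len(after.assignments) == len(assignments)


class TestLedger:
    def flows_to_ledger(self, flows):
        """Build before/after assignments realizing (initial, removed,
        reassigned_in) flows per cluster, then the ledger."""
        before, after = {}, {}
        names = {}
        counter = 0
        clusters = list(flows)
        for c, (name, initial, removed, arrived) in enumerate(flows.values()):
            names[c] = name
            for j in range(initial):
                i = f"i{counter}"
                counter += 1
                before[i] = c
                after[i] = c if j >= removed else (c + 1) % len(flows)
        # fix arrivals: reassign the removed items to realize reassigned_in
        movers = [i for i in before if before[i] != after[i]]
        targets = []
        for c, (_, _, _, arrived) in enumerate(flows.values()):
            targets += [c] * arrived
        assert len(movers) == len(targets), "flow table must conserve items"
        for i, c in zip(movers, targets):
            after[i] = c
        return build_ledger(before, after, names), names

    def test_reported_row_arithmetic(self):
        # rows with known flows: 126-0+82=208, 19-12+11=18, 13-0+19=32
        flows = {
            "uem": ("Upper Extremity Mobility", 126, 0, 82),
            "fi": ("Functional Independence", 19, 12, 11),
            "fat": ("Fatigue", 13, 0, 19),
            "pool": ("Donor", 100, 100, 0),
        }
        ledger, _ = self.flows_to_ledger(flows)
        row = ledger.row("Upper Extremity Mobility")
        assert (row["initial_size"], row["outliers_removed"], row["reassigned_in"],
                row["final_size"]) == (126, 0, 82, 208)
        row = ledger.row("Functional Independence")
        assert row["final_size"] == 19 - 12 + 11 == 18
        row = ledger.row("Fatigue")
        assert row["final_size"] == 13 - 0 + 19 == 32
        assert ledger.row("Donor")["status"] == "removed"

    def test_statuses(self):
        before = {"a": 0, "b": 0, "c": 1}
        after = {"a": 2, "b": 2, "c": 1}
        ledger = build_ledger(before, after, {0: "gone", 1: "stable", 2: "born"})
        frame = ledger.frame.set_index("name")
        assert frame.loc["gone", "status"] == "removed"
        assert frame.loc["gone", "outliers_removed"] == 2  # 100% of initial
        assert frame.loc["born", "status"] == "new"
        assert frame.loc["born", "reassigned_in"] == frame.loc["born", "final_size"]
        assert frame.loc["stable", "status"] == "kept"

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            build_ledger({"a": 0}, {"a": 0, "b": 0})

    def test_rows_ordered_by_descending_final_size(self):
        before = {f"i{j}": j % 3 for j in range(30)}
        after = dict(before)
        for j in range(6):
            after[f"i{j * 3}"] = (j % 3 + 1) % 3
        frame = build_ledger(before, after).frame
        assert list(frame["final_size"]) == sorted(frame["final_size"], reverse=True)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=8, max_size=40),
        st.lists(st.integers(0, 6), min_size=8, max_size=40),
    )
    def test_balance_and_conservation_for_random_curations(self, b_labels, a_labels):
        n = min(len(b_labels), len(a_labels))
        before = {f"i{j}": b_labels[j] for j in range(n)}
        after = {f"i{j}": a_labels[j] for j in range(n)}
        ledger = build_ledger(before, after)
        f = ledger.frame
        assert (
            f["final_size"] == f["initial_size"] - f["outliers_removed"] + f["reassigned_in"]
        ).all()
        assert f["final_size"].sum() == f["initial_size"].sum() == n

    def test_display_table_has_reporting_columns(self):
        ledger = build_ledger({"a": 0, "b": 1}, {"a": 0, "b": 0}, {0: "kept", 1: "gone"})
        table = ledger.to_table()
        assert list(table.columns) == [
            "Name",
            "Initial size",
            "Outliers removed (%)",
            "Outliers reassigned (%)",
            "Final size",
        ]
        assert "(Removed)" in table["Name"].iloc[-1]


class TestOutcomeSet:
    def make_clustering(self, n_clusters=24, per=3):
        assignments = {f"i{c}_{j}": c for c in range(n_clusters) for j in range(per)}
        names = {c: f"Domain {c:02d}" for c in range(n_clusters)}
        return assignments, names

    def test_one_entry_per_named_cluster(self, tmp_path):
        assignments, names = self.make_clustering()
        with pytest.warns(UserWarning):  # definitions missing
            outcome = emit_outcome_set(assignments, names, path=tmp_path / "cos")
        assert len(outcome.clusters) == 24
        assert (tmp_path / "cos.json").exists() and (tmp_path / "cos.csv").exists()

    def test_roundtrip(self, tmp_path):
        assignments, names = self.make_clustering(4)
        defs = {n: f"definition of {n}" for n in names.values()}
        outcome = emit_outcome_set(assignments, names, defs, path=tmp_path / "cos")
        back = load_outcome_set(tmp_path / "cos")
        assert back.clusters == outcome.clusters

    def test_clusters_ordered_by_descending_size(self):
        assignments = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 2}
        names = {0: "mid", 1: "big", 2: "small"}
        with pytest.warns(UserWarning):
            outcome = emit_outcome_set(assignments, names)
        assert outcome.names() == ["big", "mid", "small"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            emit_outcome_set({"a": 0, "b": 1}, {0: "same", 1: "same"})

    def test_unnamed_cluster_rejected(self):
        with pytest.raises(ValueError, match="name"):
            emit_outcome_set({"a": 0, "b": 1}, {0: "only"})


def test_end_to_end_curation_pass(small_world, backend):
    """Cluster, flag outliers, auto-reassign, ledger the result."""
    from itembank.embedding import embed_sentences, fit_reduce

    cleaned, truth, _ = small_world
    emb = embed_sentences(cleaned.items, backend)
    _, reduced = fit_reduce(emb, 10)
    res = AnchoredKMeans(reduced, k=4, seed=1).fit()
    outliers = detect_outliers(res, reduced, tau=0.0)
    after = reassign_items(res, outliers, embeddings=reduced)
    ledger = build_ledger(res, after)
    f = ledger.frame
    assert f["initial_size"].sum() == f["final_size"].sum() == len(cleaned.items)
    n_out = sum(len(v) for v in outliers.values())
    assert f["reassigned_in"].sum() == n_out
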