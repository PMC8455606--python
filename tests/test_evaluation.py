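import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import cellont as co
from cellont.evaluation import _pr_auc


@pytest.fixture(scope="module")
def lineage_graph():
    terms = [
        co.OntologyTerm("CL:root", "cell"),
        co.OntologyTerm("CL:lym", "lymphocyte", parent_ids=["CL:root"]),
        co.OntologyTerm("CL:t", "T cell", parent_ids=["CL:lym"]),
        co.OntologyTerm("CL:b", "B cell", parent_ids=["CL:lym"]),
        co.OntologyTerm("CL:mye", "myeloid cell", parent_ids=["CL:root"]),
    ]
    return co.build_graph(terms)


class TestMutualExclusivity:
    def test_ancestor_dropped_descendant_kept(self, lineage_graph):
        labels = {"c1": "CL:lym", "c2": "CL:t", "c3": "CL:mye"}
        kept = co.filter_mutually_exclusive(labels, lineage_graph)
        assert kept == {"CL:t", "CL:mye"}

    def test_no_overlap_keeps_all(self, lineage_graph):
        labels = {"c1": "CL:t", "c2": "CL:b", "c3": "CL:mye"}
        assert co.filter_mutually_exclusive(labels, lineage_graph) == {
            "CL:t", "CL:b", "CL:mye",
        }

    def test_chain_keeps_only_deepest(self, lineage_graph):
        labels = {"c1": "CL:root", "c2": "CL:lym", "c3": "CL:t"}
        assert co.filter_mutually_exclusive(labels, lineage_graph) == {"CL:t"}

    def test_unknown_label_errors(self, lineage_graph):
        with pytest.raises(ValueError, match="CL:unknown"):
            co.filter_mutually_exclusive({"c1": "CL:unknown"}, lineage_graph)


class TestMakeSplit:
    def labels_for(self, n_terms, cells_per_term):
        return {
            f"t{t}.c{c}": f"T:{t}"
            for t in range(n_terms)
            for c in range(cells_per_term)
        }

    def test_unseen_count(self):
        split = co.make_split(self.labels_for(10, 5), k=0.5, seed=0)
        assert len(split.unseen_term_ids) == 5
        assert len(split.seen_term_ids) == 5

    def test_one_fold_train_four_test(self):
        labels = self.labels_for(2, 100)
        split = co.make_split(labels, k=0.0, seed=1)
        for term in split.seen_term_ids:
            train = [c for c in split.train_cell_ids if labels[c] == term]
            test = [c for c in split.test_cell_ids if labels[c] == term]
            assert len(train) == 20 and len(test) == 80

    def test_unseen_cells_all_in_test(self):
        labels = self.labels_for(10, 8)
        split = co.make_split(labels, k=0.4, seed=2)
        unseen = set(split.unseen_term_ids)
        for cell, term in labels.items():
            if term in unseen:
                assert cell in set(split.test_cell_ids)
                assert cell not in set(split.train_cell_ids)

    def test_train_test_disjoint_and_deterministic(self):
        labels = self.labels_for(8, 10)
        s1 = co.make_split(labels, k=0.3, seed=7)
        s2 = co.make_split(labels, k=0.3, seed=7)
        assert set(s1.train_cell_ids).isdisjoint(s1.test_cell_ids)
        assert s1.to_dict() == s2.to_dict()
        s3 = co.make_split(labels, k=0.3, seed=8)
        assert s3.seen_term_ids != s1.seen_term_ids or s3.train_cell_ids != s1.train_cell_ids

    @pytest.mark.parametrize("k", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_invariants_across_unseen_fractions(self, k):
        labels = self.labels_for(20, 10)
        split = co.make_split(labels, k=k, seed=0)
        assert len(split.unseen_term_ids) == int(round(k * 20))
        unseen = set(split.unseen_term_ids)
        train_terms = {labels[c] for c in split.train_cell_ids}
        assert not (train_terms & unseen)
        for term in split.seen_term_ids:
            n_train = sum(labels[c] == term for c in split.train_cell_ids)
            n_test = sum(labels[c] == term for c in split.test_cell_ids)
            assert (n_train, n_test) == (2, 8)

    def test_all_unseen_errors(self):
        with pytest.raises(ValueError):
            co.make_split(self.labels_for(4, 2), k=0.99, seed=0)


def oracle_auroc(scores, truth):
    """Pairwise comparison oracle (ties count half)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_auprc(scores, truth):
    """Brute-force PR-curve oracle: sweep every threshold, trapezoid rule."""
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    n_pos = t.sum()
    points = [(0.0, 1.0)]  # recall 0 anchored at precision 1
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # all items tied at this threshold
            tp += t[j]
            fp += 1 - t[j]
            j += 1
        points.append((tp / n_pos, tp / (tp + fp)))
        i = j
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p1 + p0) / 2
    return area


class TestMacroMetrics:
    def test_unweighted_mean_of_per_class_auroc(self):
        # class 0 perfectly ranked (AUROC 1), class 1 antiranked on purpose
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.4], [0.2, 0.3]])
        truth = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        m = co.macro_metrics(scores, truth, ["A", "B"], seed=0)
        a = roc_auc_score(truth[:, 0], scores[:, 0])
        b = roc_auc_score(truth[:, 1], scores[:, 1])
        assert m["macro_auroc"] == pytest.approx((a + b) / 2)

    def test_perfect_scores_give_one(self):
        truth = np.zeros((40, 4), dtype=int)
        truth[np.arange(40), np.repeat(np.arange(4), 10)] = 1
        m = co.macro_metrics(truth.astype(float), truth, list("abcd"), seed=0)
        assert m["macro_auroc"] == 1.0
        assert m["macro_auprc"] == 1.0

    def test_seen_unseen_aggregates(self):
        rng = np.random.default_rng(0)
        truth = np.zeros((60, 3), dtype=int)
        truth[np.arange(60), rng.integers(0, 3, 60)] = 1
        scores = rng.uniform(size=(60, 3))
        m = co.macro_metrics(scores, truth, list("abc"),
                             seen_term_ids=["a"], unseen_term_ids=["b", "c"], seed=0)
        per = m["per_class_auroc"]
        assert m["macro_auroc_seen"] == pytest.approx(per["a"])
        assert m["macro_auroc_unseen"] == pytest.approx((per["b"] + per["c"]) / 2)

    def test_class_without_positives_skipped(self):
        truth = np.zeros((10, 2), dtype=int)
        truth[:, 0] = 1
        truth[0, 0] = 0
        with pytest.warns(UserWarning, match="no positives"):
            m = co.macro_metrics(np.random.default_rng(0).uniform(size=(10, 2)),
                                 truth, ["a", "b"], seed=0)
        assert "b" not in m["per_class_auroc"]


class TestMetricOracles:
    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            truth = (rng.uniform(size=n) < 0.3).astype(int)
            if truth.sum() in (0, n):
                continue
            scores = rng.normal(size=n)
            assert roc_auc_score(truth, scores) == pytest.approx(
                oracle_auroc(scores, truth), abs=1e-9
            )

    def test_auprc_matches_pr_curve_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            truth = (rng.uniform(size=n) < 0.3).astype(int)
            if truth.sum() in (0, n):
                continue
            scores = rng.normal(size=n)  # continuous: no ties
            assert _pr_auc(truth, scores) == pytest.approx(
                oracle_auprc(scores, truth), abs=1e-9
            )


class TestAccuracyAtK:
    def test_rank_three_counts_at_k3(self):
        scores = np.array([[0.5, 0.3, 0.2, 0.0]])
        assert co.accuracy_at_k(scores, np.array([2]), k=3) == 1.0
        assert co.accuracy_at_k(scores, np.array([3]), k=3) == 0.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores = rng.uniform(size=(20, 10))
            true_idx = rng.integers(0, 10, size=20)
            assert co.accuracy_at_k(scores, true_idx, 5) >= co.accuracy_at_k(
                scores, true_idx, 3
            )

    def test_uniform_scores_tie_break_by_index(self):
        scores = np.ones((1, 6))
        assert co.accuracy_at_k(scores, np.array([2]), k=3) == 1.0
        assert co.accuracy_at_k(scores, np.array([3]), k=3) == 0.0

    def test_oversized_k_clipped(self):
        with pytest.warns(UserWarning, match="clipping"):
            acc = co.accuracy_at_k(np.ones((2, 3)), np.array([0, 2]), k=9)
        assert acc == 1.0


class TestNearestUnseen:
    def test_adjacent_unseen_chosen(self, lineage_graph):
        scores = np.array([[1.0]])  # single seen term: T cell
        out = co.assign_nearest_unseen(scores, lineage_graph, ["CL:t"], ["CL:b"])
        assert out == ["CL:b"]

    def test_equidistant_tie_breaks_lexicographically(self, lineage_graph):
        scores = np.array([[1.0]])  # from CL:lym, both CL:t and CL:b are 1 hop
        out = co.assign_nearest_unseen(scores, lineage_graph, ["CL:lym"], ["CL:t", "CL:b"])
        assert out == ["CL:b"]

    def test_empty_unseen_keeps_seen_assignment(self, lineage_graph):
        scores = np.array([[0.2, 0.8]])
        out = co.assign_nearest_unseen(scores, lineage_graph, ["CL:t", "CL:b"], [])
        assert out == ["CL:b"]
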