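"""ROC oracles, Welch tests, correlation network, discretization, rule mining."""

import itertools

import numpy as np
import pytest

from metaboselect.interpret import (
    correlation_network,
    discretize_equal_width,
    feature_t_tests,
    mine_rules,
    roc_auc,
    roc_curve_points,
)
from tests.conftest import make_table


def brute_force_auc(scores, labels) -> float:
    """Concordant-pair count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([1, 1, 1, -1, -1, -1])
        result = roc_auc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], labels)
        assert result.auc == 1.0
        assert result.sensitivity_at_best == 1.0
        assert result.specificity_at_best == 1.0

    def test_null_scores_near_half(self, rng):
        n = 2000
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        result = roc_auc(rng.normal(size=n), labels)
        assert abs(result.auc - 0.5) < 0.05
        assert result.ci_low <= result.auc <= result.ci_high

    def test_six_sample_tie_case_matches_pair_count(self):
        scores = [0.9, 0.5, 0.4, 0.5, 0.3, 0.1]
        labels = np.array([1, 1, 1, -1, -1, -1])
        result = roc_auc(scores, labels)
        assert result.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            n_pos = int(rng.integers(2, n - 1))
            labels = np.array([1] * n_pos + [-1] * (n - n_pos))
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            result = roc_auc(scores, labels)
            assert result.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_degenerate_scores_flagged(self):
        labels = np.array([1, 1, -1, -1])
        result = roc_auc([0.5, 0.5, 0.5, 0.5], labels)
        assert result.degenerate
        assert result.auc == 0.5

    def test_curve_endpoints(self, rng):
        labels = np.array([1, 1, -1, -1, 1])
        pts = roc_curve_points(rng.normal(size=5), labels)
        assert tuple(pts[0][:2]) == (0.0, 0.0)
        assert tuple(pts[-1][:2]) == (1.0, 1.0)


class TestFeatureTTests:
    def test_identical_groups_p_one(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        table = make_table(x, labels=np.array([1, 1, 1, -1, -1, -1]))
        t, p = feature_t_tests(table, ["f0"])["f0"]
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_welch_3v3(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        x = np.concatenate([a, b])[:, None]
        table = make_table(x, labels=np.array([1, 1, 1, -1, -1, -1]))
        t, p = feature_t_tests(table, ["f0"])["f0"]
        # Welch formula by hand
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy import stats

        p_manual = 2 * stats.t.sf(abs(t_manual), df)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert p == pytest.approx(p_manual, abs=1e-10)

    def test_planted_effect_power_at_cohort_size(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            labels = np.where(np.arange(111) < 55, 1, -1)
            x = r.normal(size=(111, 1))
            x[:, 0] += labels * 0.75  # total separation d = 1.5
            table = make_table(x, labels=labels)
            _, p = feature_t_tests(table, ["f0"])["f0"]
            if p < 1e-4:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_both_groups_constant_undefined(self):
        x = np.ones((6, 1))
        table = make_table(x, labels=np.array([1, 1, 1, -1, -1, -1]))
        t, p = feature_t_tests(table, ["f0"])["f0"]
        assert np.isnan(t) and np.isnan(p)


class TestCorrelationNetwork:
    def test_duplicated_pair_single_unit_edge(self, rng):
        x = rng.normal(size=(30, 3))
        x[:, 1] = x[:, 0]
        net = correlation_network(make_table(x), ["f0", "f1", "f2"], threshold=0.99)
        assert len(net.edges) == 1
        a, b, r = net.edges[0]
        assert {a, b} == {"f0", "f1"}
        assert r == pytest.approx(1.0)

    def test_cluster_triangle_positive(self):
        from metaboselect.synthdata import SynthSpec, generate_dataset

        spec = SynthSpec(
            n_case=100, n_control=100, n_features=5, n_informative=0,
            cluster_sizes=[3], within_cluster_r=0.9, seed=2,
        )
        table = generate_dataset(spec)
        net = correlation_network(table, table.feature_ids[:3], threshold=0.5)
        assert len(net.edges) == 3
        assert all(r > 0 for _, _, r in net.edges)

    def test_impossible_threshold_empty(self, rng):
        net = correlation_network(make_table(rng.normal(size=(20, 4))),
                                  [f"f{j}" for j in range(4)], threshold=1.01)
        assert net.edges == []

    def test_zero_variance_excluded_with_warning(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            net = correlation_network(make_table(x), ["f0", "f1", "f2"])
        assert net.nodes == ["f0", "f1"]

    def test_graphml_round_trip(self, tmp_path, rng):
        import networkx as nx

        x = rng.normal(size=(25, 3))
        x[:, 1] = x[:, 0] + 0.05 * rng.normal(size=25)
        net = correlation_network(make_table(x), ["f0", "f1", "f2"], threshold=0.8)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(net.edges)


class TestDiscretize:
    def test_even_range_edges(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        table = make_table(x, labels=np.array([1, 1, 1, -1, -1]))
        tx = discretize_equal_width(table, ["f0"], n_bins=4)
        labels = [items[0][1] for items in tx]
        # bins: (-inf,1], (1,2], (2,3], (3,inf)
        assert labels[0] == labels[1]  # 0 and 1 in the lowest bin
        assert len({labels[1], labels[2], labels[3], labels[4]}) == 4
        assert labels[0].startswith("(-inf")
        assert labels[4].endswith("inf)")

    def test_one_item_per_feature(self, rng):
        table = make_table(rng.normal(size=(12, 5)))
        tx = discretize_equal_width(table, table.feature_ids, n_bins=4)
        assert len(tx) == 12
        for items in tx:
            assert len(items) == 5
            assert {f for f, _ in items} == set(table.feature_ids)

    def test_membership_matches_brute_force(self, rng):
        """Two samples share an interval item iff brute-force binning agrees."""
        x = rng.normal(size=(50, 3))
        table = make_table(x)
        tx = discretize_equal_width(table, table.feature_ids, n_bins=4)
        for j in range(3):
            lo, hi = x[:, j].min(), x[:, j].max()
            edges = [lo + (hi - lo) * k / 4 for k in (1, 2, 3)]
            bins = [sum(x[i, j] > e for e in edges) for i in range(50)]
            labels = [tx[i][j][1] for i in range(50)]
            for a in range(50):
                for b in range(50):
                    assert (bins[a] == bins[b]) == (labels[a] == labels[b])

    def test_equal_frequency_bins_are_balanced(self, rng):
        x = rng.normal(size=(40, 1))
        table = make_table(x)
        tx = discretize_equal_width(table, ["f0"], n_bins=4, equal_frequency=True)
        from collections import Counter

        counts = Counter(items[0][1] for items in tx)
        assert len(counts) == 4
        assert all(c == 10 for c in counts.values())

    def test_constant_feature_flagged(self, rng):
        x = np.column_stack([np.full(10, 2.0), rng.normal(size=10)])
        with pytest.warns(UserWarning, match="constant"):
            tx = discretize_equal_width(make_table(x), ["f0", "f1"])
        assert all(items[0][1] == "(-inf − inf)" for items in tx)

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            discretize_equal_width(make_table(rng.normal(size=(5, 2))), ["f0"], n_bins=1)


def brute_force_rules(transactions, min_support, min_confidence):
    """Exhaustive rule enumeration for small item universes."""
    tx = [frozenset(t) for t in transactions]
    items = sorted({i for t in tx for i in t})
    n = len(tx)
    rules = set()
    for k in range(2, len(items) + 1):
        for itemset in itertools.combinations(items, k):
            s = frozenset(itemset)
            support = sum(1 for t in tx if s <= t) / n
            if support < min_support:
                continue
            for consequent in s:
                ante = s - {consequent}
                ante_support = sum(1 for t in tx if ante <= t) / n
                conf = support / ante_support
                if conf >= min_confidence:
                    rules.add((ante, consequent, round(support, 12), round(conf, 12)))
    return rules


class TestMineRules:
    TOY = [
        [("A", "1"), ("B", "1"), ("C", "1")],
        [("A", "1"), ("B", "1")],
        [("A", "1"), ("C", "1")],
        [("B", "1"), ("C", "1")],
        [("A", "1"), ("B", "1"), ("C", "1")],
        [("C", "1")],
    ]

    def test_deterministic_implication_confidence_one(self):
        tx = [[("A", "1"), ("B", "1")], [("A", "1"), ("B", "1")], [("B", "1")]]
        rules = mine_rules(tx, min_support=0.5, min_confidence=0.99)
        found = {(frozenset(r.antecedent), r.consequent): r.confidence for r in rules}
        assert found[(frozenset({("A", "1")}), ("B", "1"))] == 1.0

    def test_toy_matches_brute_force(self):
        got = {
            (r.antecedent, r.consequent, round(r.support, 12), round(r.confidence, 12))
            for r in mine_rules(self.TOY, min_support=0.3, min_confidence=0.6)
        }
        expected = brute_force_rules(self.TOY, 0.3, 0.6)
        assert got == expected

    def test_raising_support_never_adds_rules(self):
        low = mine_rules(self.TOY, min_support=0.2, min_confidence=0.6)
        high = mine_rules(self.TOY, min_support=0.5, min_confidence=0.6)
        as_set = lambda rules: {(r.antecedent, r.consequent) for r in rules}
        assert as_set(high) <= as_set(low)

    def test_thresholds_respected(self):
        rules = mine_rules(self.TOY, min_support=0.3, min_confidence=0.7)
        assert all(r.support >= 0.3 and r.confidence >= 0.7 for r in rules)

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            mine_rules(self.TOY, min_support=0.0, min_confidence=0.5)
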