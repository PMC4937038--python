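"""Interpretation of the predictive features and models.

Covers ROC/AUC with DeLong confidence intervals, per-feature Welch t-tests,
the signed Pearson correlation network between predictive features, and
association-rule mining (Apriori) on equal-width-discretized intensities —
the last two expose the parent-ion/fragment structure behind groups of
co-selected features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dataio import FeatureTable

__all__ = [
    "RocResult",
    "CorrelationNetwork",
    "AssociationRule",
    "roc_auc",
    "roc_curve_points",
    "feature_t_tests",
    "correlation_network",
    "discretize_equal_width",
    "mine_rules",
]


# ----------------------------------------------------------------------
# ROC / AUC
# ----------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity_at_best: float
    specificity_at_best: float
    n_pos: int
    n_neg: int
    degenerate: bool = False


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance from positive/negative scores."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = _midrank(all_scores)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values (structural components)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(probabilities: Sequence[float], labels: Sequence[int], alpha: float = 0.05) -> RocResult:
    """Empirical AUC with DeLong CI and the Youden-optimal operating point.

    AUC uses the Mann–Whitney identity with tie correction (ties count one
    half).  If all scores are identical the result is flagged degenerate with
    AUC 0.5.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = probs[y == 1]
    neg = probs[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for ROC analysis")
    if np.allclose(probs, probs[0]):
        return RocResult(0.5, 0.5, 0.5, 1.0, 0.0, len(pos), len(neg), degenerate=True)
    auc, var = _delong_variance(pos, neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci_low = max(0.0, auc - half)
    ci_high = min(1.0, auc + half)
    # Youden's J over all empirical thresholds
    best_j, best_sens, best_spec = -np.inf, 0.0, 0.0
    for thr in np.unique(probs):
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1
        if j > best_j:
            best_j, best_sens, best_spec = j, sens, spec
    return RocResult(
        auc=auc,
        ci_low=min(ci_low, auc),
        ci_high=max(ci_high, auc),
        sensitivity_at_best=best_sens,
        specificity_at_best=best_spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def bootstrap_roc_ci(
    probabilities: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the AUC (optional alternative)."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = probs[y == 1]
    neg = probs[y == -1]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        aucs[b], _ = _delong_variance(bp, bn)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def roc_curve_points(probabilities: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """(fpr, tpr, threshold) rows of the full empirical ROC curve."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = probs[y == 1]
    neg = probs[y == -1]
    thresholds = np.concatenate([[np.inf], np.unique(probs)[::-1]])
    rows = []
    for thr in thresholds:
        tpr = float(np.mean(pos >= thr))
        fpr = float(np.mean(neg >= thr))
        rows.append((fpr, tpr, thr))
    return np.array(rows)


# ----------------------------------------------------------------------
# Univariate t-tests
# ----------------------------------------------------------------------

def feature_t_tests(table: FeatureTable, features: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Welch two-sample t and two-sided p per feature.

    Features with zero variance in both groups get ``(nan, nan)`` as an
    explicit undefined marker.
    """
    sub = table.subset_features(list(features))
    mask = sub.labels == 1
    for m in (mask, ~mask):
        if m.sum() < 2:
            raise ValueError("t-tests require at least two samples per class")
    out: dict[str, tuple[float, float]] = {}
    for j, fid in enumerate(sub.feature_ids):
        a, b = sub.intensities[mask, j], sub.intensities[~mask, j]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            out[fid] = (float("nan"), float("nan"))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out[fid] = (float(t), float(p))
    return out


# ----------------------------------------------------------------------
# Correlation network
# ----------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    """Signed Pearson network among predictive features."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, r in self.edges:
            g.add_edge(a, b, r=float(r), sign="positive" if r >= 0 else "negative")
        nx.write_graphml(g, path)


def correlation_network(
    table: FeatureTable, features: Sequence[str], threshold: float = 0.5
) -> CorrelationNetwork:
    """All pairwise Pearson correlations among ``features``; edges at |r| ≥ threshold.

    Edge weights keep their sign (positive/negative correlation classes).
    Zero-variance features are excluded with a warning.
    """
    if len(features) < 2:
        raise ValueError("a network needs at least two features")
    sub = table.subset_features(list(features))
    sd = sub.intensities.std(axis=0, ddof=1)
    keep = [f for f, s in zip(sub.feature_ids, sd) if s > 0]
    dropped = [f for f, s in zip(sub.feature_ids, sd) if s == 0]
    if dropped:
        warnings.warn(f"zero-variance features excluded from network: {dropped}", stacklevel=2)
    sub = sub.subset_features(keep)
    r = np.corrcoef(sub.intensities, rowvar=False)
    edges = []
    for i, j in itertools.combinations(range(len(keep)), 2):
        if abs(r[i, j]) >= threshold:
            edges.append((keep[i], keep[j], float(r[i, j])))
    return CorrelationNetwork(nodes=keep, edges=edges, threshold=threshold)


# ----------------------------------------------------------------------
# Discretization and association rules
# ----------------------------------------------------------------------

Item = tuple[str, str]  # (feature id, interval label)


def _interval_label(lo: float, hi: float) -> str:
    lo_s = "-inf" if lo == -np.inf else f"{lo:.6f}"
    hi_s = "inf" if hi == np.inf else f"{hi:.6f}"
    # lowest interval closed on the right, highest open: "(lo − hi]" / "(lo − inf)"
    closer = ")" if hi == np.inf else "]"
    return f"({lo_s} − {hi_s}{closer}"


def discretize_equal_width(
    table: FeatureTable,
    features: Sequence[str],
    n_bins: int = 4,
    equal_frequency: bool = False,
) -> list[list[Item]]:
    """Per-sample transactions of (feature, interval) items.

    Each feature's [min, max] range splits into ``n_bins`` equal-width
    intervals; the lowest interval is open at −∞ and the highest at +∞ so
    out-of-range values still map to an item.  With ``equal_frequency=True``
    the inner edges are the feature's quantiles instead.  Constant features
    yield a single all-covering interval (flagged with a warning).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    sub = table.subset_features(list(features))
    x = sub.intensities
    n, p = x.shape
    labels_per_feature: list[list[str]] = []
    bins_per_feature: list[np.ndarray] = []
    for j, fid in enumerate(sub.feature_ids):
        lo, hi = float(x[:, j].min()), float(x[:, j].max())
        if lo == hi:
            warnings.warn(f"constant feature {fid!r}: single-interval item", stacklevel=2)
            edges = np.array([])
            labels = [_interval_label(-np.inf, np.inf)]
        else:
            if equal_frequency:
                edges = np.quantile(x[:, j], np.arange(1, n_bins) / n_bins)
            else:
                edges = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
            bounds = [-np.inf, *edges, np.inf]
            labels = [
                _interval_label(bounds[k], bounds[k + 1]) for k in range(n_bins)
            ]
        labels_per_feature.append(labels)
        bins_per_feature.append(edges)
    transactions: list[list[Item]] = []
    for i in range(n):
        items: list[Item] = []
        for j, fid in enumerate(sub.feature_ids):
            edges = bins_per_feature[j]
            k = int(np.searchsorted(edges, x[i, j], side="left")) if edges.size else 0
            items.append((fid, labels_per_feature[j][k]))
        transactions.append(items)
    return transactions


@dataclass
class AssociationRule:
    """antecedent → consequent with exact support and confidence."""

    antecedent: frozenset
    consequent: Item
    support: float
    confidence: float


def _apriori(transactions: list[frozenset], min_support: float) -> dict[frozenset, float]:
    """Level-wise frequent-itemset search; returns itemset → support."""
    n = len(transactions)
    counts: dict[frozenset, int] = {}
    for t in transactions:
        for item in t:
            key = frozenset([item])
            counts[key] = counts.get(key, 0) + 1
    frequent = {k: c / n for k, c in counts.items() if c / n >= min_support}
    all_frequent = dict(frequent)
    current = sorted(frequent, key=lambda s: sorted(s))
    k = 1
    while current:
        k += 1
        candidates: set[frozenset] = set()
        items_in_current = sorted({i for s in current for i in s})
        current_set = set(current)
        for s in current:
            for item in items_in_current:
                if item not in s:
                    cand = s | {item}
                    if len(cand) == k and all(
                        cand - {x} in current_set for x in cand
                    ):
                        candidates.add(cand)
        counts = {c: 0 for c in candidates}
        for t in transactions:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        next_level = {c: cnt / n for c, cnt in counts.items() if cnt / n >= min_support}
        all_frequent.update(next_level)
        current = list(next_level)
    return all_frequent


def mine_rules(
    transactions: Iterable[Iterable[Item]],
    min_support: float,
    min_confidence: float,
) -> list[AssociationRule]:
    """Apriori frequent itemsets, then single-consequent rule generation.

    Supports and confidences are exact counts over the transactions; rules
    are sorted by confidence, then support (both descending), then by item
    labels for determinism.
    """
    tx = [frozenset(t) for t in transactions]
    if not tx:
        raise ValueError("no transactions")
    if min_support <= 0:
        raise ValueError("min_support must be positive (combinatorial guard)")
    frequent = _apriori(tx, min_support)
    rules: list[AssociationRule] = []
    for itemset, support in frequent.items():
        if len(itemset) < 2:
            continue
        for consequent in itemset:
            antecedent = itemset - {consequent}
            ante_support = frequent.get(antecedent)
            if ante_support is None:
                ante_support = sum(1 for t in tx if antecedent <= t) / len(tx)
            confidence = support / ante_support if ante_support else 0.0
            if confidence >= min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=frozenset(antecedent),
                        consequent=consequent,
                        support=support,
                        confidence=confidence,
                    )
                )
    rules.sort(
        key=lambda r: (-r.confidence, -r.support, sorted(r.antecedent), r.consequent)
    )
    return rules


def rules_to_text(rules: list[AssociationRule]) -> str:
    """Delimited-text rendering: antecedent, consequent, support, confidence."""
    lines = ["antecedent\tconsequent\tsupport\tconfidence"]
    for r in rules:
        ante = " & ".join(f"{f} = {iv}" for f, iv in sorted(r.antecedent))
        cons = f"{r.consequent[0]} = {r.consequent[1]}"
        lines.append(f"{ante}\t{cons}\t{r.support:.6f}\t{r.confidence:.6f}")
    return "\n".join(lines) + "\n"
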