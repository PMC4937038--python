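"""Feature-ranking routes feeding the stability-consensus stage.

Ten routes are produced in the full workflow, combining a redundancy filter
(none, Pearson-correlation, or mutual-information) with a ranking engine:

* ``ANOVA-p`` — per-feature one-way two-group F-test, ranked by ascending p;
* ``RF-MdAcc`` / ``RF-MdGini`` (and their ``Cor-`` filtered variants) —
  random-forest permutation importance (mean decrease in OOB accuracy) or
  total Gini-impurity decrease, taken from the best of several replicate
  forests (smallest out-of-bag error);
* ``SVM-RFE-W`` — absolute weights of a single linear-SVM hyperplane;
* ``MI-SVM-RFE-Acc/Kap`` and ``Cor-RF-RFE-Acc/Kap`` — recursive feature
  elimination with an SVM or forest inner model, subset quality scored by
  leave-one-out accuracy or Cohen's kappa, final rank = elimination order
  (survivors best).

Forests are built tree-by-tree over explicit bootstrap draws so that
out-of-bag masks, OOB error and permutation importance are reproducible from
a single master seed: replicate ``r`` derives its generator from
``SeedSequence([master_seed, r])`` and is reproducible in isolation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .dataio import FeatureTable
from .preprocess import is_unit_scaled

logger = logging.getLogger("metaboselect")

METHOD_IDS = (
    "RF-MdAcc",
    "RF-MdGini",
    "Cor-RF-MdAcc",
    "Cor-RF-MdGini",
    "Cor-RF-RFE-Acc",
    "Cor-RF-RFE-Kap",
    "MI-SVM-RFE-Acc",
    "MI-SVM-RFE-Kap",
    "SVM-RFE-W",
    "ANOVA-p",
)


@dataclass
class RankingResult:
    """An ordered feature list with per-feature scores under a named method."""

    method_id: str
    ordered_features: list[str]
    scores: np.ndarray
    score_direction: Literal["descending", "ascending"]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ordered_features) != len(self.scores):
            raise ValueError("one score per ordered feature required")
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("duplicate features in ranking")

    def take_top(self, n: int) -> list[str]:
        return take_top(self, n)


def take_top(ranking: RankingResult, n: int) -> list[str]:
    """The first ``n`` feature ids of a ranking (best first)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ranking.ordered_features):
        raise ValueError(
            f"n={n} exceeds ranking length {len(ranking.ordered_features)}"
        )
    return ranking.ordered_features[:n]


@dataclass
class ConfusionMatrix:
    """Counts of true/false positives/negatives for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


# ----------------------------------------------------------------------
# ANOVA route
# ----------------------------------------------------------------------

def anova_rank(table: FeatureTable, p_cut: float = 0.1) -> RankingResult:
    """Per-feature one-way two-group ANOVA, ranked by ascending p-value.

    For two groups the F statistic equals the squared pooled-variance t
    statistic.  BH-adjusted p-values are attached in ``metadata['adjusted_p']``
    (aligned with ``ordered_features``) and the number of features below
    ``p_cut`` in ``metadata['n_below_cut']`` — that count defines the route's
    top set.
    """
    table.require_both_classes()
    x = table.intensities
    mask = table.labels == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.f_oneway(x[mask], x[~mask])
    pvals = np.atleast_1d(np.asarray(pvals, dtype=float))
    # a feature constant within both groups but differing between them has
    # F = inf -> p = 0; scipy may emit nan when all values are identical
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    order = np.argsort(pvals, kind="stable")
    ordered = [table.feature_ids[j] for j in order]
    return RankingResult(
        method_id="ANOVA-p",
        ordered_features=ordered,
        scores=pvals[order],
        score_direction="ascending",
        metadata={
            "adjusted_p": adjusted[order],
            "p_cut": p_cut,
            "n_below_cut": int(np.sum(pvals < p_cut)),
        },
    )


def anova_top_set(ranking: RankingResult) -> list[str]:
    """The ANOVA route's top set: all features with p below the entry cut."""
    return ranking.ordered_features[: ranking.metadata["n_below_cut"]]


# ----------------------------------------------------------------------
# Random forest built over explicit bootstrap draws
# ----------------------------------------------------------------------

def mtry_for(p: int, factor: float = 2.0) -> int:
    """Variables tried per node: ``factor``·⌈√p⌉, capped at p."""
    m = int(factor * math.ceil(math.sqrt(p)))
    if m > p:
        logger.debug("mtry %d exceeds feature count %d; clipped", m, p)
        m = p
    return max(1, min(m, p))


class Forest:
    """Bagged classification trees with explicit out-of-bag bookkeeping."""

    def __init__(self, n_trees: int = 2000, mtry: int | None = None, mtry_factor: float = 2.0):
        self.n_trees = int(n_trees)
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.mtry = mtry
        self.mtry_factor = mtry_factor
        self.trees: list[DecisionTreeClassifier] = []
        self.inbag: np.ndarray | None = None  # (n_trees, n) bootstrap counts

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "Forest":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else mtry_for(p, self.mtry_factor)
        self._X, self._y = X, y
        self.trees = []
        self.inbag = np.zeros((self.n_trees, n), dtype=np.int32)
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            np.add.at(self.inbag[t], idx, 1)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
        return self

    # -- out-of-bag -----------------------------------------------------
    def _tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n) matrix of per-tree predicted labels."""
        X = np.asarray(X, dtype=np.float32)
        return np.stack([tree.predict(X) for tree in self.trees])

    def oob_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """Majority-vote OOB label per sample and a validity mask.

        Samples that were in-bag for every tree are masked out (possible at
        very small ensembles); callers exclude them from error denominators.
        """
        preds = self._tree_predictions(self._X)
        oob = self.inbag == 0  # (n_trees, n)
        votes_pos = ((preds == 1) & oob).sum(axis=0)
        votes_neg = ((preds == -1) & oob).sum(axis=0)
        covered = (votes_pos + votes_neg) > 0
        n_uncovered = int(np.sum(~covered))
        if n_uncovered:
            logger.info("%d samples never out-of-bag; excluded from OOB error", n_uncovered)
        # tie-break toward the negative (Control) class, deterministically
        labels = np.where(votes_pos > votes_neg, 1, -1)
        return labels, covered

    def oob_error(self) -> float:
        labels, covered = self.oob_predictions()
        if not covered.any():
            return float("nan")
        return float(np.mean(labels[covered] != self._y[covered]))

    # -- importances ----------------------------------------------------
    def gini_importance(self) -> np.ndarray:
        """Total Gini-impurity decrease per feature, averaged over trees."""
        total = np.zeros(self._X.shape[1])
        for tree in self.trees:
            total += tree.tree_.compute_feature_importances(normalize=False)
        return total / len(self.trees)

    def mdacc_importance(self, rng: np.random.Generator, chunk: int = 64) -> np.ndarray:
        """Mean decrease in per-tree OOB accuracy when a feature is permuted.

        One permutation is drawn per feature and applied across all trees;
        each tree is scored on its own out-of-bag samples, and the accuracy
        drop is averaged over trees.
        """
        X, y = self._X, self._y
        n, p = X.shape
        oob = self.inbag == 0
        oob_sizes = oob.sum(axis=1).astype(float)
        usable = oob_sizes > 0
        base_preds = self._tree_predictions(X)  # (T, n)
        base_correct = base_preds == y[None, :]
        base_acc = np.where(
            usable, (base_correct & oob).sum(axis=1) / np.maximum(oob_sizes, 1), np.nan
        )
        perms = [rng.permutation(n) for _ in range(p)]
        importance = np.zeros(p)
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            k = len(feats)
            stacked = np.tile(X, (k, 1))
            for bi, j in enumerate(feats):
                stacked[bi * n : (bi + 1) * n, j] = X[perms[j], j]
            for t, tree in enumerate(self.trees):
                if not usable[t]:
                    continue
                preds = tree.predict(stacked).reshape(k, n)
                correct = preds == y[None, :]
                acc = (correct & oob[t][None, :]).sum(axis=1) / oob_sizes[t]
                importance[start : start + k] += base_acc[t] - acc
        n_usable = int(usable.sum())
        return importance / max(n_usable, 1)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def rf_rank(
    table: FeatureTable,
    metric: Literal["MdAcc", "MdGini"] = "MdAcc",
    n_trees: int = 2000,
    mtry_factor: float = 2.0,
    replicates: int = 50,
    seed: int = 0,
    filter_tag: str = "",
) -> RankingResult:
    """Rank features by random-forest importance from the best replicate.

    ``replicates`` independent forests are trained; the one with the smallest
    out-of-bag error is kept and its importance (permutation ``MdAcc`` or
    impurity ``MdGini``) defines the ranking.  ``filter_tag`` ("" or "Cor-")
    prefixes the method id so filtered and unfiltered routes stay distinct.
    """
    table.require_both_classes()
    X, y = table.intensities, table.labels
    best_forest: Forest | None = None
    best_err = np.inf
    best_rng_state: int = 0
    for r in range(replicates):
        rng = _replicate_rng(seed, r)
        forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(X, y, rng)
        err = forest.oob_error()
        if err < best_err:
            best_err, best_forest, best_rng_state = err, forest, r
    assert best_forest is not None
    if metric == "MdAcc":
        imp = best_forest.mdacc_importance(_replicate_rng(seed, 10_000 + best_rng_state))
    elif metric == "MdGini":
        imp = best_forest.gini_importance()
    else:
        raise ValueError(f"unknown RF importance metric {metric!r}")
    order = np.argsort(-imp, kind="stable")
    return RankingResult(
        method_id=f"{filter_tag}RF-{metric}",
        ordered_features=[table.feature_ids[j] for j in order],
        scores=imp[order],
        score_direction="descending",
        metadata={"oob_error": best_err, "replicate": best_rng_state},
    )


# ----------------------------------------------------------------------
# Linear SVM and recursive feature elimination
# ----------------------------------------------------------------------

def _fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    return np.abs(np.asarray(svm.coef_).ravel())


def loocv_predictions(X: np.ndarray, y: np.ndarray, fit_predict) -> np.ndarray:
    """Pooled leave-one-out predictions; ``fit_predict(Xtr, ytr, xte)`` → label."""
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        preds[i] = fit_predict(X[tr], y[tr], X[i : i + 1])
    return preds


def _svm_fit_predict(Xtr: np.ndarray, ytr: np.ndarray, xte: np.ndarray):
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(Xtr, ytr)
    return svm.predict(xte)[0]


def _loocv_quality(X: np.ndarray, y: np.ndarray, fit_predict) -> tuple[float, float]:
    preds = loocv_predictions(X, y, fit_predict)
    acc = float(np.mean(preds == y))
    kappa = float(cohen_kappa_score(y, preds)) if len(set(preds)) > 0 else 0.0
    return acc, kappa


def _rfe(
    table: FeatureTable,
    importance_fn,
    quality_fn,
    elimination_fraction: float = 0.5,
) -> tuple[list[str], dict[int, tuple[float, float]]]:
    """Generic recursive feature elimination.

    Each round scores the current subset (``quality_fn`` → (acc, kappa)),
    computes per-feature importances on the full data, and drops the lowest
    fraction.  Returns the final ranking (best first: survivors, then dropped
    batches in reverse round order, each batch ordered by importance) and the
    per-subset-size quality trace.
    """
    if not 0 < elimination_fraction <= 1:
        raise ValueError("elimination_fraction must be in (0, 1]")
    ids = list(table.feature_ids)
    current = list(range(len(ids)))
    eliminated: list[list[int]] = []
    quality: dict[int, tuple[float, float]] = {}
    X = table.intensities
    y = table.labels
    while True:
        sub = X[:, current]
        quality[len(current)] = quality_fn(sub, y)
        if len(current) == 1:
            break
        imp = importance_fn(sub, y)
        n_keep = math.ceil(len(current) * (1 - elimination_fraction))
        n_keep = min(max(n_keep, 1), len(current) - 1)
        order = np.argsort(imp, kind="stable")  # ascending: worst first
        drop_local = order[: len(current) - n_keep]
        # batch recorded worst-first
        eliminated.append([current[j] for j in sorted(drop_local, key=lambda j: imp[j])])
        keep_local = sorted(order[len(current) - n_keep :])
        current = [current[j] for j in keep_local]
    # survivors best; then batches in reverse elimination order, best-first
    ranked: list[int] = list(current)
    for batch in reversed(eliminated):
        ranked.extend(reversed(batch))
    return [ids[j] for j in ranked], quality


def svm_rfe_rank(
    table: FeatureTable,
    metric: Literal["W", "Acc", "Kappa"] = "W",
    elimination_fraction: float = 0.5,
    filter_tag: str = "",
) -> RankingResult:
    """Linear-SVM feature ranking.

    ``metric="W"`` ranks by absolute hyperplane weight from a single fit on
    the full (unit-variance-scaled) table.  ``"Acc"``/``"Kappa"`` run RFE:
    each round drops the lowest-|w| fraction, subset quality is pooled
    leave-one-out accuracy or Cohen's kappa; the final rank is the
    elimination order with survivors best.
    """
    table.require_both_classes()
    if not is_unit_scaled(table):
        warnings.warn(
            "svm_rfe_rank expects a unit-variance-scaled table; proceeding anyway",
            stacklevel=2,
        )
    X, y = table.intensities, table.labels
    if metric == "W":
        w = _fit_linear_svm(X, y)
        order = np.argsort(-w, kind="stable")
        return RankingResult(
            method_id=f"{filter_tag}SVM-RFE-W",
            ordered_features=[table.feature_ids[j] for j in order],
            scores=w[order],
            score_direction="descending",
        )
    if metric not in ("Acc", "Kappa"):
        raise ValueError(f"unknown SVM-RFE metric {metric!r}")
    ranked, quality = _rfe(
        table,
        importance_fn=lambda Xs, ys: _fit_linear_svm(Xs, ys),
        quality_fn=lambda Xs, ys: _loocv_quality(Xs, ys, _svm_fit_predict),
        elimination_fraction=elimination_fraction,
    )
    qi = 0 if metric == "Acc" else 1
    best_size = max(quality, key=lambda size: (quality[size][qi], -size))
    short = "Acc" if metric == "Acc" else "Kap"
    return RankingResult(
        method_id=f"{filter_tag}SVM-RFE-{short}",
        ordered_features=ranked,
        scores=np.arange(len(ranked), 0, -1, dtype=float),
        score_direction="descending",
        metadata={"subset_quality": quality, "best_subset_size": best_size},
    )


def rf_rfe_rank(
    table: FeatureTable,
    metric: Literal["Acc", "Kappa"] = "Acc",
    cv: Literal["loocv", "oob"] = "loocv",
    elimination_fraction: float = 0.5,
    n_trees: int = 2000,
    mtry_factor: float = 2.0,
    replicates: int = 50,
    seed: int = 0,
    filter_tag: str = "",
) -> RankingResult:
    """RFE with a random-forest inner model; per-round importances are MdAcc.

    Subset quality per round is pooled LOOCV accuracy/kappa (``cv="loocv"``)
    or the forest's own out-of-bag estimate (``cv="oob"``, cheaper).  The
    replicate whose best round maximizes the chosen metric is returned.
    """
    table.require_both_classes()

    def run_one(rep: int):
        rng = _replicate_rng(seed, rep)

        def importance(Xs, ys):
            forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xs, ys, rng)
            return forest.mdacc_importance(rng)

        if cv == "loocv":
            def rf_fit_predict(Xtr, ytr, xte):
                f = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xtr, ytr, rng)
                preds = np.stack([t.predict(np.asarray(xte, dtype=np.float32)) for t in f.trees])
                pos = int(np.sum(preds == 1))
                return 1 if pos > len(f.trees) - pos else -1

            quality = lambda Xs, ys: _loocv_quality(Xs, ys, rf_fit_predict)
        elif cv == "oob":
            def quality(Xs, ys):
                f = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xs, ys, rng)
                labels, covered = f.oob_predictions()
                acc = float(np.mean(labels[covered] == ys[covered]))
                kappa = float(cohen_kappa_score(ys[covered], labels[covered]))
                return acc, kappa
        else:
            raise ValueError(f"unknown cv scheme {cv!r}")
        return _rfe(table, importance, quality, elimination_fraction)

    qi = 0 if metric == "Acc" else 1
    best = None
    for rep in range(replicates):
        ranked, quality = run_one(rep)
        score = max(q[qi] for q in quality.values())
        if best is None or score > best[0]:
            best_size = max(quality, key=lambda size: (quality[size][qi], -size))
            best = (score, ranked, quality, best_size, rep)
    assert best is not None
    _, ranked, quality, best_size, rep = best
    short = "Acc" if metric == "Acc" else "Kap"
    return RankingResult(
        method_id=f"{filter_tag}RF-RFE-{short}",
        ordered_features=ranked,
        scores=np.arange(len(ranked), 0, -1, dtype=float),
        score_direction="descending",
        metadata={
            "subset_quality": quality,
            "best_subset_size": best_size,
            "replicate": rep,
            "cv": cv,
        },
    )
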