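"""End-to-end selection workflow: filters → ten ranking routes → consensus.

This glue module runs the ten ranking routes of the reference design on one
feature table, assembles their top sets into a formal context, and applies
the ≥k-technique consensus rule.  Routes sharing computation are paired:
one replicate-selected forest yields both the MdAcc and MdGini rankings, and
one RFE pass per replicate yields both the accuracy- and kappa-scored
variants (the metric picks the best replicate/subset, not the order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import FeatureTable
from .filters import FilterResult, correlation_filter, mutual_info_filter
from .preprocess import uv_scale
from .rankers import (
    Forest,
    RankingResult,
    _replicate_rng,
    _rfe,
    _fit_linear_svm,
    _loocv_quality,
    _svm_fit_predict,
    anova_rank,
    anova_top_set,
    svm_rfe_rank,
    take_top,
)
from .stability import FormalContext, build_context, consensus_select

logger = logging.getLogger("metaboselect")


@dataclass
class SelectionRun:
    """Everything the selection stage produced, for downstream use."""

    rankings: dict[str, RankingResult]
    top_sets: dict[str, list[str]]
    context: FormalContext
    consensus: list[str]
    filters: dict[str, FilterResult]


def _best_forest(X, y, n_trees, mtry_factor, replicates, seed):
    best = None
    for r in range(replicates):
        rng = _replicate_rng(seed, r)
        forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(X, y, rng)
        err = forest.oob_error()
        if best is None or err < best[1]:
            best = (forest, err, r)
    return best


def _rf_ranking_pair(
    table: FeatureTable, n_trees, mtry_factor, replicates, seed, filter_tag=""
) -> tuple[RankingResult, RankingResult]:
    """MdAcc and MdGini rankings from the smallest-OOB replicate forest."""
    forest, err, rep = _best_forest(
        table.intensities, table.labels, n_trees, mtry_factor, replicates, seed
    )
    mdacc = forest.mdacc_importance(_replicate_rng(seed, 10_000 + rep))
    gini = forest.gini_importance()
    out = []
    for metric, imp in (("MdAcc", mdacc), ("MdGini", gini)):
        order = np.argsort(-imp, kind="stable")
        out.append(
            RankingResult(
                method_id=f"{filter_tag}RF-{metric}",
                ordered_features=[table.feature_ids[j] for j in order],
                scores=imp[order],
                score_direction="descending",
                metadata={"oob_error": err, "replicate": rep},
            )
        )
    return out[0], out[1]


def _rf_rfe_pair(
    table: FeatureTable, n_trees, mtry_factor, replicates, seed, cv, filter_tag=""
) -> tuple[RankingResult, RankingResult]:
    """Acc- and Kappa-scored RF-RFE rankings; one RFE pass per replicate.

    With ``cv="oob"`` each round fits a single forest that supplies both the
    subset quality (OOB vote accuracy/kappa) and the MdAcc elimination order.
    """
    from sklearn.metrics import cohen_kappa_score

    runs = []
    for rep in range(replicates):
        rng = _replicate_rng(seed, rep)
        holder: dict = {}

        def quality(Xs, ys):
            forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xs, ys, rng)
            holder["forest"], holder["p"] = forest, Xs.shape[1]
            if cv == "oob":
                labels, covered = forest.oob_predictions()
                acc = float(np.mean(labels[covered] == ys[covered]))
                kap = float(cohen_kappa_score(ys[covered], labels[covered]))
                return acc, kap
            from .rankers import _loocv_quality as lq

            def rf_fit_predict(Xtr, ytr, xte):
                f = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xtr, ytr, rng)
                preds = np.stack(
                    [t.predict(np.asarray(xte, dtype=np.float32)) for t in f.trees]
                )
                pos = int(np.sum(preds == 1))
                return 1 if pos > len(f.trees) - pos else -1

            return lq(Xs, ys, rf_fit_predict)

        def importance(Xs, ys):
            forest = holder.get("forest")
            if forest is None or holder.get("p") != Xs.shape[1]:
                forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(Xs, ys, rng)
            return forest.mdacc_importance(rng)

        ranked, qual = _rfe(table, importance, quality)
        runs.append((ranked, qual))
    out = []
    for metric, qi, short in (("Acc", 0, "Acc"), ("Kappa", 1, "Kap")):
        best_rep = max(
            range(len(runs)), key=lambda r: max(q[qi] for q in runs[r][1].values())
        )
        ranked, qual = runs[best_rep]
        best_size = max(qual, key=lambda size: (qual[size][qi], -size))
        out.append(
            RankingResult(
                method_id=f"{filter_tag}RF-RFE-{short}",
                ordered_features=ranked,
                scores=np.arange(len(ranked), 0, -1, dtype=float),
                score_direction="descending",
                metadata={
                    "subset_quality": qual,
                    "best_subset_size": best_size,
                    "replicate": best_rep,
                    "cv": cv,
                },
            )
        )
    return out[0], out[1]


def _svm_rfe_pair(table: FeatureTable, filter_tag="") -> tuple[RankingResult, RankingResult]:
    """Acc- and Kappa-scored SVM-RFE rankings from a single RFE pass."""
    ranked, qual = _rfe(
        table,
        importance_fn=lambda Xs, ys: _fit_linear_svm(Xs, ys),
        quality_fn=lambda Xs, ys: _loocv_quality(Xs, ys, _svm_fit_predict),
    )
    out = []
    for qi, short in ((0, "Acc"), (1, "Kap")):
        best_size = max(qual, key=lambda size: (qual[size][qi], -size))
        out.append(
            RankingResult(
                method_id=f"{filter_tag}SVM-RFE-{short}",
                ordered_features=ranked,
                scores=np.arange(len(ranked), 0, -1, dtype=float),
                score_direction="descending",
                metadata={"subset_quality": qual, "best_subset_size": best_size},
            )
        )
    return out[0], out[1]


def run_ten_routes(
    table: FeatureTable,
    *,
    n_trees: int = 2000,
    replicates: int = 50,
    rfe_cv: str = "oob",
    seed: int = 0,
    top_filtered: int = 200,
    top_unfiltered: int = 178,
    anova_p: float = 0.1,
    cor_threshold: float = 0.95,
    mi_threshold: float = 0.02,
    consensus_k: int = 6,
    mtry_factor: float = 2.0,
) -> SelectionRun:
    """Run the ten ranking routes and the stability consensus on one table.

    Top-set sizes are clipped to the available feature counts (a filter can
    retain fewer features than the nominal top-n).
    """
    table.require_both_classes()
    rankings: dict[str, RankingResult] = {}

    # no-filter routes: RF pair, SVM-RFE-W (scaled), ANOVA
    rf_acc, rf_gini = _rf_ranking_pair(table, n_trees, mtry_factor, replicates, seed)
    rankings[rf_acc.method_id] = rf_acc
    rankings[rf_gini.method_id] = rf_gini
    scaled = uv_scale(table)
    rankings["SVM-RFE-W"] = svm_rfe_rank(scaled, metric="W")
    anova = anova_rank(table, p_cut=anova_p)
    rankings["ANOVA-p"] = anova

    # correlation-filter routes
    cor_result = correlation_filter(table, threshold=cor_threshold)
    cor_table = table.subset_features(cor_result.retained)
    cor_acc, cor_gini = _rf_ranking_pair(
        cor_table, n_trees, mtry_factor, replicates, seed + 1, filter_tag="Cor-"
    )
    rankings[cor_acc.method_id] = cor_acc
    rankings[cor_gini.method_id] = cor_gini
    rfe_acc, rfe_kap = _rf_rfe_pair(
        cor_table, n_trees, mtry_factor, max(1, replicates // 10), seed + 2, rfe_cv,
        filter_tag="Cor-",
    )
    rankings[rfe_acc.method_id] = rfe_acc
    rankings[rfe_kap.method_id] = rfe_kap

    # mutual-information routes
    mi_result = mutual_info_filter(table, threshold=mi_threshold)
    mi_table = uv_scale(table.subset_features(mi_result.retained))
    svm_acc, svm_kap = _svm_rfe_pair(mi_table, filter_tag="MI-")
    rankings[svm_acc.method_id] = svm_acc
    rankings[svm_kap.method_id] = svm_kap

    top_sets: dict[str, list[str]] = {}
    for mid, ranking in rankings.items():
        if mid == "ANOVA-p":
            top_sets[mid] = anova_top_set(ranking)
        elif mid.startswith(("Cor-", "MI-")):
            top_sets[mid] = take_top(ranking, min(top_filtered, len(ranking.ordered_features)))
        else:
            top_sets[mid] = take_top(ranking, min(top_unfiltered, len(ranking.ordered_features)))
    top_sets = {m: s for m, s in top_sets.items() if s}
    context = build_context(top_sets)
    consensus = consensus_select(context, k=min(consensus_k, len(top_sets)))
    logger.info(
        "ten-route selection: %d features in context, %d in consensus (k=%d)",
        len(context.objects), len(consensus), consensus_k,
    )
    return SelectionRun(
        rankings=rankings,
        top_sets=top_sets,
        context=context,
        consensus=consensus,
        filters={"correlation": cor_result, "mutual_information": mi_result},
    )
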