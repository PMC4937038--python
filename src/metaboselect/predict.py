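"""Prediction routes on the consensus feature subset, plus evaluation.

Three routes mirror the reference workflow:

* :func:`rf_predict_nested` — a random forest on the consensus subset,
  ranked by permutation importance, evaluated on nested top-k subsets
  (48 → 40 → 30 → 20 → 10 → 5) over repeated stratified 75/25 splits;
* :func:`varsel_rf` — backwards variable elimination with a forest, dropping
  the least important fraction each round and keeping the variable set at the
  minimum out-of-bag error, replicated to find the stable intersection;
* :func:`logistic_pipeline` — the four-stage logistic selection: univariable
  entry at p<0.25, collinearity pruning to max |r| ≤ 0.5, reduction to a
  10-feature shortlist by outcome correlation, and bidirectional stepwise AIC
  on the final multiple logistic model.

Evaluation metrics derive from confusion counts; denominators of zero yield
``None`` (an explicit undefined marker), never a silent zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .dataio import FeatureTable
from .rankers import ConfusionMatrix, Forest, _replicate_rng

logger = logging.getLogger("metaboselect")


@dataclass
class EvalReport:
    """Confusion counts and the six derived performance metrics."""

    confusion: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    misclassification: float | None
    oob_error: float | None
    n_features: int
    model_id: str


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(
    cm: ConfusionMatrix,
    model_id: str = "",
    n_features: int = 0,
    oob_error: float | None = None,
) -> EvalReport:
    """The six standard metrics of a confusion matrix.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/n; precision = tp/(tp+fp);
    misclassification = 1 − accuracy.  Undefined ratios are ``None``.
    """
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    return EvalReport(
        confusion=cm,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        accuracy=accuracy,
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        misclassification=None if accuracy is None else 1.0 - accuracy,
        oob_error=oob_error,
        n_features=n_features,
        model_id=model_id,
    )


# ----------------------------------------------------------------------
# Route 1: RF on nested top-k subsets
# ----------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx: list[int] = []
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
    train = np.zeros(len(labels), dtype=bool)
    train[train_idx] = True
    return train


def rf_predict_nested(
    table: FeatureTable,
    consensus: Sequence[str],
    subset_sizes: Sequence[int] = (48, 40, 30, 20, 10, 5),
    split_frac: float = 0.75,
    replications: int = 100,
    n_trees: int = 2000,
    mtry_factor: float = 2.0,
    seed: int = 0,
) -> list[EvalReport]:
    """Forest performance over nested subsets of the consensus features.

    A forest on the full consensus subset supplies the permutation-importance
    (MdAcc) ranking; nested subsets of the requested sizes are cut from that
    ranking and each is evaluated over ``replications`` stratified
    ``split_frac`` train/test splits.  Confusion counts are pooled across
    splits; the report's OOB error is the mean over the evaluation forests.
    Sizes exceeding the consensus are skipped with a warning.
    """
    table.require_both_classes()
    sub = table.subset_features(list(consensus))
    if any(0 < s < sub.n_features for s in subset_sizes):
        rng = _replicate_rng(seed, 0)
        ranker = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(
            sub.intensities, sub.labels, rng
        )
        imp = ranker.mdacc_importance(_replicate_rng(seed, 1))
        order = np.argsort(-imp, kind="stable")
        ranked_ids = [sub.feature_ids[j] for j in order]
    else:  # only whole-set evaluations requested: ranking is irrelevant
        ranked_ids = list(sub.feature_ids)

    reports: list[EvalReport] = []
    for size in subset_sizes:
        if size > len(ranked_ids):
            warnings.warn(
                f"subset size {size} exceeds consensus size {len(ranked_ids)}; skipped",
                stacklevel=2,
            )
            continue
        feats = ranked_ids[:size]
        sub_k = sub.subset_features(feats)
        X, y = sub_k.intensities, sub_k.labels
        pooled = ConfusionMatrix(0, 0, 0, 0)
        oob_errors: list[float] = []
        for rep in range(replications):
            rep_rng = _replicate_rng(seed, 1000 + 97 * size + rep)
            train = _stratified_split(y, split_frac, rep_rng)
            forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(
                X[train], y[train], rep_rng
            )
            preds = _forest_predict(forest, X[~train])
            cm = ConfusionMatrix.from_predictions(y[~train], preds)
            pooled = ConfusionMatrix(
                pooled.tp + cm.tp, pooled.fp + cm.fp, pooled.tn + cm.tn, pooled.fn + cm.fn
            )
            oob_errors.append(forest.oob_error())
        reports.append(
            confusion_metrics(
                pooled,
                model_id=f"{size}-Rf-acc",
                n_features=size,
                oob_error=float(np.nanmean(oob_errors)),
            )
        )
    return reports


def _forest_predict(forest: Forest, X: np.ndarray) -> np.ndarray:
    preds = np.stack([t.predict(np.asarray(X, dtype=np.float32)) for t in forest.trees])
    pos = (preds == 1).sum(axis=0)
    return np.where(pos > len(forest.trees) - pos, 1, -1)


# ----------------------------------------------------------------------
# Route 2: backwards variable elimination (varSelRF-style)
# ----------------------------------------------------------------------

def varsel_rf(
    table: FeatureTable,
    consensus: Sequence[str],
    drop_frac: float = 0.2,
    replications: int = 100,
    n_trees: int = 2000,
    mtry_factor: float = 2.0,
    seed: int = 0,
    rule: Literal["min", "1se"] = "min",
) -> tuple[list[str], list[list[str]]]:
    """Backwards elimination with a forest, replicated.

    Per replicate: fit a forest on the current variable set, record its OOB
    error, drop the least-important ``drop_frac`` of variables (permutation
    importance), refit, and repeat down to two variables; the variable set at
    the minimum OOB error is returned (``rule="1se"`` instead takes the
    smallest set within one standard error of the minimum).  Across
    replicates the intersection is the "stable" set; an empty intersection is
    returned as empty with a logged notice.
    """
    if len(consensus) < 2:
        raise ValueError("varsel_rf requires at least two consensus features")
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    sub = table.subset_features(list(consensus))
    per_replicate: list[list[str]] = []
    n = sub.n_samples
    for rep in range(replications):
        rng = _replicate_rng(seed, 2_000_000 + rep)
        current = list(range(sub.n_features))
        path: list[tuple[list[int], float]] = []
        while True:
            X = sub.intensities[:, current]
            forest = Forest(n_trees=n_trees, mtry_factor=mtry_factor).fit(
                X, sub.labels, rng
            )
            err = forest.oob_error()
            path.append((list(current), err))
            if len(current) <= 2:
                break
            imp = forest.mdacc_importance(rng)
            n_drop = max(1, int(math.floor(drop_frac * len(current))))
            n_drop = min(n_drop, len(current) - 2)
            worst = np.argsort(imp, kind="stable")[:n_drop]
            keep = sorted(set(range(len(current))) - set(int(w) for w in worst))
            current = [current[j] for j in keep]
        errors = np.array([e for _, e in path])
        if rule == "min":
            # smallest set among those attaining the minimum error
            best = min(
                (i for i in range(len(path)) if errors[i] == errors.min()),
                key=lambda i: len(path[i][0]),
            )
        else:  # 1-s.e. rule
            se = math.sqrt(errors.min() * (1 - errors.min()) / n)
            ok = [i for i in range(len(path)) if errors[i] <= errors.min() + se]
            best = min(ok, key=lambda i: len(path[i][0]))
        per_replicate.append(sorted(sub.feature_ids[j] for j in path[best][0]))
    stable = set(per_replicate[0])
    for s in per_replicate[1:]:
        stable &= set(s)
    if not stable:
        logger.info("varsel_rf: empty intersection across %d replicates", replications)
    return sorted(stable), per_replicate


# ----------------------------------------------------------------------
# Route 3: logistic-regression selection pipeline
# ----------------------------------------------------------------------

@dataclass
class LogitSelectionTrace:
    """Full record of the four-stage logistic selection."""

    univariable_p: dict[str, float]
    survivors: list[str]
    corr_eliminations: list[tuple[str, float]]
    shortlist_eliminations: list[tuple[str, float, float]]
    shortlist: list[str]
    final_terms: list[str]
    coefficients: dict[str, float]
    aic_path: list[tuple[str, float]]
    separation_flags: list[str] = field(default_factory=list)


def _ridge_logit(X: np.ndarray, y01: np.ndarray, alpha: float = 1e-4, max_iter: int = 100):
    """Newton/IRLS logistic fit with a small L2 penalty on all terms.

    Keeps coefficients and Wald p-values finite under complete separation.
    Returns (params, p_values, loglik).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y01 - mu) - alpha * beta
        hess = X.T @ (X * w[:, None]) + alpha * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    hess = X.T @ (X * w[:, None]) + alpha * np.eye(k)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    from scipy import stats as _st

    z = beta / se
    pvals = 2 * _st.norm.sf(np.abs(z))
    loglik = float(np.sum(y01 * np.log(mu) + (1 - y01) * np.log(1 - mu)))
    return beta, pvals, loglik


def _logit_fit(X: np.ndarray, y01: np.ndarray, ridge_alpha: float = 1e-4):
    """ML logistic fit with ridge fallback on separation/divergence.

    Returns (params, p_values, aic, separated_flag); design matrix X carries
    its own intercept column.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, X).fit(disp=0, maxiter=200)
            separated = (not res.mle_retvals.get("converged", False)) or bool(
                np.any(~np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50)
            )
            if not separated:
                return np.asarray(res.params), np.asarray(res.pvalues), float(res.aic), False
        except Exception:
            pass
    beta, pvals, loglik = _ridge_logit(X, y01, alpha=ridge_alpha)
    aic = 2 * X.shape[1] - 2 * loglik
    return beta, pvals, float(aic), True


def logistic_pipeline(
    table: FeatureTable,
    consensus: Sequence[str],
    entry_p: float = 0.25,
    max_r: float = 0.5,
    shortlist: int = 10,
) -> LogitSelectionTrace:
    """The four-stage logistic selection on the consensus subset.

    1. Univariable logistic fits; keep features with coefficient p < ``entry_p``.
    2. Collinearity pruning: while the largest pairwise |r| exceeds
       ``max_r``, drop from the worst pair the feature with the larger mean
       |r| to the others, recording the |r| at removal.
    3. If more than ``shortlist`` remain, iteratively drop the feature with
       the smallest |point-biserial correlation with the outcome| (ties by
       larger univariable p) until ``shortlist`` remain.
    4. Multiple logistic fit on the shortlist, reduced by bidirectional
       stepwise AIC starting from the full model.
    """
    table.require_both_classes()
    sub = table.subset_features(list(consensus))
    y01 = (sub.labels == 1).astype(float)
    ids = sub.feature_ids
    X = sub.intensities

    # stage 1: univariable fits
    uni_p: dict[str, float] = {}
    separation_flags: list[str] = []
    for j, fid in enumerate(ids):
        design = sm.add_constant(X[:, j : j + 1])
        _, pvals, _, separated = _logit_fit(design, y01)
        uni_p[fid] = float(pvals[1])
        if separated:
            separation_flags.append(fid)
    survivors = [f for f in ids if uni_p[f] < entry_p]

    # stage 2: collinearity pruning (loop invariant: max |r| among kept > max_r)
    corr_elims: list[tuple[str, float]] = []
    kept = list(survivors)
    while len(kept) >= 2:
        cols = [ids.index(f) for f in kept]
        r = np.abs(np.corrcoef(X[:, cols], rowvar=False))
        np.fill_diagonal(r, 0.0)
        worst = r.max()
        if worst <= max_r:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(r), r.shape)
        mean_i = r[i_loc].sum() / (len(kept) - 1)
        mean_j = r[j_loc].sum() / (len(kept) - 1)
        if mean_i > mean_j:
            drop = i_loc
        elif mean_j > mean_i:
            drop = j_loc
        else:
            drop = max(i_loc, j_loc, key=lambda l: kept[l])
        corr_elims.append((kept[drop], float(worst)))
        del kept[drop]

    # stage 3: reduce to the shortlist by outcome correlation, then p-value
    short_elims: list[tuple[str, float, float]] = []
    current = list(kept)
    while len(current) > shortlist:
        cols = [ids.index(f) for f in current]
        r_out = np.array(
            [abs(float(np.corrcoef(X[:, c], y01)[0, 1])) for c in cols]
        )
        # lexicographic: smallest |r with outcome|, then largest univariable p
        order = sorted(
            range(len(current)),
            key=lambda l: (r_out[l], -uni_p[current[l]], current[l]),
        )
        drop = order[0]
        short_elims.append((current[drop], float(r_out[drop]), uni_p[current[drop]]))
        del current[drop]
    shortlist_ids = list(current)

    # stage 4: bidirectional stepwise AIC from the full shortlist model
    final_terms, coefficients, aic_path = _stepwise_aic(
        X, y01, ids, shortlist_ids
    )
    return LogitSelectionTrace(
        univariable_p=uni_p,
        survivors=survivors,
        corr_eliminations=corr_elims,
        shortlist_eliminations=short_elims,
        shortlist=shortlist_ids,
        final_terms=final_terms,
        coefficients=coefficients,
        aic_path=aic_path,
        separation_flags=separation_flags,
    )


def _model_aic(X: np.ndarray, y01: np.ndarray, ids: list[str], terms: list[str]) -> float:
    cols = [ids.index(f) for f in terms]
    design = sm.add_constant(X[:, cols]) if cols else np.ones((len(y01), 1))
    _, _, aic, _ = _logit_fit(design, y01)
    return aic


def _stepwise_aic(
    X: np.ndarray, y01: np.ndarray, ids: list[str], shortlist_ids: list[str]
):
    current = list(shortlist_ids)
    aic = _model_aic(X, y01, ids, current)
    aic_path: list[tuple[str, float]] = [("start", aic)]
    while True:
        candidates: list[tuple[float, str, str]] = []
        for f in current:
            trial = [g for g in current if g != f]
            candidates.append((_model_aic(X, y01, ids, trial), "drop", f))
        for f in shortlist_ids:
            if f not in current:
                candidates.append((_model_aic(X, y01, ids, current + [f]), "add", f))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_aic, action, feat = candidates[0]
        if best_aic >= aic - 1e-9:
            break
        aic = best_aic
        if action == "drop":
            current = [g for g in current if g != feat]
        else:
            current = current + [feat]
        aic_path.append((f"{action} {feat}", aic))
    cols = [ids.index(f) for f in current]
    design = sm.add_constant(X[:, cols]) if cols else np.ones((len(y01), 1))
    beta, _, _, _ = _logit_fit(design, y01)
    names = ["const"] + current if cols else ["const"]
    coefficients = {name: float(b) for name, b in zip(names, beta)}
    return current, coefficients, aic_path


# ----------------------------------------------------------------------
# LOOCV probabilities
# ----------------------------------------------------------------------

def loocv_probabilities(
    model_spec: Literal["logistic", "rf"] | Callable,
    table: FeatureTable,
    features: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample held-out class-1 probability under leave-one-out CV.

    ``model_spec`` may be ``"logistic"`` (ridge-stabilized ML fit),
    ``"rf"`` (fraction of tree votes) or a callable
    ``fit(Xtr, ytr) -> predict_proba(Xte) -> array``.
    """
    sub = table.subset_features(list(features))
    X, y = sub.intensities, sub.labels
    y01 = (y == 1).astype(float)
    n = len(y)
    for cls in (1, -1):
        if np.sum(y == cls) < 2:
            raise ValueError("LOOCV requires at least two samples per class")
    probs = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        if model_spec == "logistic":
            design = sm.add_constant(X[tr], has_constant="add")
            beta, _, _, _ = _logit_fit(design, y01[tr])
            eta = float(np.concatenate([[1.0], X[i]]) @ beta)
            probs[i] = 1.0 / (1.0 + math.exp(-eta))
        elif model_spec == "rf":
            rng = _replicate_rng(seed, 3_000_000 + i)
            forest = Forest(n_trees=n_trees).fit(X[tr], y[tr], rng)
            preds = np.stack(
                [t.predict(np.asarray(X[i : i + 1], dtype=np.float32)) for t in forest.trees]
            )
            probs[i] = float(np.mean(preds == 1))
        elif callable(model_spec):
            predict_proba = model_spec(X[tr], y[tr])
            probs[i] = float(np.asarray(predict_proba(X[i : i + 1])).ravel()[0])
        else:
            raise ValueError(f"unknown model_spec {model_spec!r}")
    return probs
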