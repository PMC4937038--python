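"""Redundancy and dependency filters applied before feature ranking.

Untargeted LC-MS tables carry heavy redundancy — one metabolite shows up as a
parent ion plus fragments and adducts — which distorts some variable-importance
measures.  Two filters address this:

* :func:`correlation_filter` greedily breaks up groups of near-collinear
  features (pairwise scan; from the worst offending pair, the member with the
  larger mean absolute correlation to everything else is dropped), so that no
  retained pair exceeds the |r| threshold.
* :func:`mutual_info_filter` scores each feature by its average mutual
  information with all other features, using the Gaussian closed form
  MI = −½·ln(1−r²) (in nats), and retains features whose average falls below
  the threshold — low average MI marking approximately independent features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dataio import FeatureTable
from .preprocess import ZeroVarianceError

__all__ = ["FilterResult", "correlation_filter", "mutual_info_filter", "gaussian_mi_matrix"]


@dataclass
class FilterResult:
    """Outcome of a redundancy/dependency filter.

    ``removed`` maps each dropped feature id to ``(partner_id, statistic)`` —
    for the correlation filter, the other member of the offending pair and the
    |r| at removal; for the MI filter, ``None`` and the feature's average MI.
    """

    retained: list[str]
    removed: dict[str, tuple[str | None, float]]
    threshold: float
    method: Literal["correlation", "mutual_information"]

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.removed)
        if overlap:
            raise ValueError(f"features both retained and removed: {sorted(overlap)}")


def _check_variance(table: FeatureTable) -> np.ndarray:
    x = table.intensities
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ZeroVarianceError([table.feature_ids[j] for j in zero])
    return x


def correlation_filter(table: FeatureTable, threshold: float = 0.95) -> FilterResult:
    """Greedy elimination of highly correlated features.

    While any pair of retained features exceeds ``threshold`` in absolute
    Pearson correlation, locate the pair with the largest |r| and drop the
    member with the larger mean absolute correlation to all remaining
    features (ties broken by lexicographic feature id).  Afterwards the
    maximum off-diagonal |r| among retained features is ≤ ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if table.n_samples < 3:
        raise ValueError("correlation filter requires ≥3 samples")
    x = _check_variance(table)
    ids = table.feature_ids
    r = np.abs(np.corrcoef(x, rowvar=False))
    if r.ndim == 0:  # single feature
        return FilterResult(list(ids), {}, threshold, "correlation")
    np.fill_diagonal(r, 0.0)
    alive = np.ones(len(ids), dtype=bool)
    removed: dict[str, tuple[str | None, float]] = {}
    while True:
        sub = np.where(alive)[0]
        rr = r[np.ix_(sub, sub)]
        worst = rr.max(initial=0.0)
        if worst <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(rr), rr.shape)
        a, b = sub[i_loc], sub[j_loc]
        mean_a = r[a, sub].sum() / (len(sub) - 1)
        mean_b = r[b, sub].sum() / (len(sub) - 1)
        if mean_a > mean_b:
            drop, keep = a, b
        elif mean_b > mean_a:
            drop, keep = b, a
        else:  # tie: drop the lexicographically larger id
            drop, keep = (a, b) if ids[a] > ids[b] else (b, a)
        alive[drop] = False
        removed[ids[drop]] = (ids[keep], float(r[a, b]))
    retained = [ids[j] for j in np.where(alive)[0]]
    return FilterResult(retained, removed, threshold, "correlation")


def gaussian_mi_matrix(x: np.ndarray) -> np.ndarray:
    """Feature×feature mutual information, MI = −½·ln(1−r²) nats.

    Symmetric, non-negative, zero diagonal by convention; exactly collinear
    pairs get MI = +inf.
    """
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log1p(-(r**2))
    np.fill_diagonal(mi, 0.0)
    return mi


def mutual_info_filter(table: FeatureTable, threshold: float = 0.02) -> FilterResult:
    """Retain features whose average MI with all other features is below threshold.

    Each feature's score is the row mean of the Gaussian MI matrix with the
    diagonal excluded; features below ``threshold`` (in nats) are considered
    approximately independent of the rest and kept.
    """
    if table.n_samples < 3:
        raise ValueError("mutual information filter requires ≥3 samples")
    x = _check_variance(table)
    ids = table.feature_ids
    p = len(ids)
    if p == 1:
        return FilterResult(list(ids), {}, threshold, "mutual_information")
    mi = gaussian_mi_matrix(x)
    avg = mi.sum(axis=1) / (p - 1)
    retained = [ids[j] for j in range(p) if avg[j] < threshold]
    removed = {ids[j]: (None, float(avg[j])) for j in range(p) if avg[j] >= threshold}
    return FilterResult(retained, removed, threshold, "mutual_information")
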