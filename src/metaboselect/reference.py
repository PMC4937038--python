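"""Published reference values from the original serum cohort study.

The original case-control cohort (55 cases who later developed type-2
diabetes vs 56 matched controls, 1195 LC-MS features) is not deposited, but
several of its printed summaries serve as inputs and worked examples here:

* ``TOP11_RANKS`` — the printed ranks of the 11 best predictive features
  under each of the ten ranking techniques (``None`` where a feature was
  absent from a route's ranking, e.g. removed by that route's filter);
* ``TOP_SET_SIZES`` — the top-set cutoff per technique (200 for filtered
  routes, 178 for unfiltered machine-learning routes, 107 for the ANOVA
  p<0.1 route);
* ``MODEL_ERROR_COUNTS`` — false-positive/false-negative counts of the five
  final predictive models, from which the printed misclassification rates
  are recomputed;
* cohort shape constants and the ANOVA significance counts.

``top11_context`` derives an honest 11×10 presence/absence incidence from
the printed ranks; ``synthetic_supplementary_context`` is a synthetic
stand-in for the full (non-deposited) feature×technique supplementary table,
constructed so that exactly 48 features reach the ≥6-technique consensus,
with the 11 printed rows embedded.
"""

from __future__ import annotations

import numpy as np

from .stability import FormalContext

N_CASES = 55
N_CONTROLS = 56
N_SAMPLES = N_CASES + N_CONTROLS
N_FEATURES = 1195
N_ANOVA_P_BELOW_01 = 107
N_BH_SIGNIFICANT = 52
N_CONSENSUS = 48

METHOD_ORDER = (
    "RF-MdAcc",
    "RF-MdGini",
    "Cor-RF-MdGini",
    "Cor-RF-MdAcc",
    "Cor-RF-RFE-Acc",
    "Cor-RF-RFE-Kap",
    "MI-SVM-RFE-Acc",
    "MI-SVM-RFE-Kap",
    "SVM-RFE-W",
    "ANOVA-p",
)

#: top-set cutoff per technique, aligned with METHOD_ORDER
TOP_SET_SIZES = (178, 178, 200, 200, 200, 200, 200, 200, 178, 107)

#: printed per-technique ranks of the 11 best predictive features
TOP11_RANKS: dict[str, tuple[int | None, ...]] = {
    "m/z 145": (1, 1, 1, 2, 46, 53, 100, 125, 323, 2),
    "m/z 97": (2, 2, 3, 1, 142, 185, 63, 67, 159, 3),
    "m/z 325": (5, 5, 7, 5, 210, 220, 38, 37, 1118, 8),
    "m/z 268": (9, 6, None, None, None, None, 168, 181, 22, 4),
    "m/z 263": (8, 7, 5, 7, 198, 249, 28, 27, 166, 5),
    "m/z 219": (13, 13, 13, 12, 84, 76, 61, 65, 1022, 12),
    "m/z 162": (104, 31, 20, 26, 211, 221, 39, 38, 103, 17),
    "m/z 288": (167, 36, 25, 29, 140, 152, None, None, 976, 22),
    "m/z 148": (43, 47, 27, 86, 87, 98, 66, 70, 471, 38),
    "m/z 198": (101, 71, 150, 496, 48, 36, 70, 84, 167, 34),
    "m/z 167": (48, 50, 45, 24, 505, 586, 144, 154, 13, 39),
}

#: (model id, false positives, false negatives) of the five final models,
#: each evaluated on the full cohort of 111 samples
MODEL_ERROR_COUNTS = (
    ("RF", 9, 13),
    ("VarSelRF", 14, 11),
    ("Logistic regression", 10, 10),
    ("Univariate top 5", 12, 14),
    ("Univariate top 11", 12, 9),
)


def top11_context() -> FormalContext:
    """11×10 presence/absence context derived from the printed ranks.

    A feature is incident with a technique when its printed rank falls
    within that technique's top-set cutoff.
    """
    objects = list(TOP11_RANKS)
    incidence = np.zeros((len(objects), len(METHOD_ORDER)), dtype=int)
    for i, feature in enumerate(objects):
        for j, rank in enumerate(TOP11_RANKS[feature]):
            if rank is not None and rank <= TOP_SET_SIZES[j]:
                incidence[i, j] = 1
    return FormalContext(objects=objects, attributes=list(METHOD_ORDER), incidence=incidence)


def synthetic_supplementary_context(seed: int = 0, n_low: int = 72) -> FormalContext:
    """Synthetic stand-in for the non-deposited feature×technique table.

    The real supplementary table lists every feature selected by at least one
    technique; it is not available, so this stand-in embeds the 11 printed
    rows of :func:`top11_context`, adds 37 synthetic rows with stability
    degree ≥6 (completing the 48-feature consensus) and ``n_low`` synthetic
    rows with degree 1–5.  Deterministic for a fixed seed.  Suitable for
    exercising the consensus rule and lattice machinery at realistic scale —
    not a reconstruction of the original table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 48]))
    base = top11_context()
    m = len(METHOD_ORDER)
    rows = [base.incidence[i] for i in range(len(base.objects))]
    objects = list(base.objects)
    for i in range(N_CONSENSUS - len(objects)):
        degree = int(rng.integers(6, m + 1))
        row = np.zeros(m, dtype=int)
        row[rng.choice(m, size=degree, replace=False)] = 1
        rows.append(row)
        objects.append(f"synthetic high {i + 1}")
    for i in range(n_low):
        degree = int(rng.integers(1, 6))
        row = np.zeros(m, dtype=int)
        row[rng.choice(m, size=degree, replace=False)] = 1
        rows.append(row)
        objects.append(f"synthetic low {i + 1}")
    return FormalContext(
        objects=objects, attributes=list(METHOD_ORDER), incidence=np.array(rows)
    )
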