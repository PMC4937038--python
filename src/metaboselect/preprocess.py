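"""Unit-variance scaling of the feature table.

Wide concentration ranges mean raw intensities would let a handful of abundant
ions dominate margin-based models; dividing every feature by its standard
deviation gives each variable the same chance to contribute.  Scaling is
applied before SVM-based methods; tree ensembles and F-tests are
scale-invariant and consume raw intensities by default.
"""

from __future__ import annotations

import numpy as np

from .dataio import FeatureTable


class ZeroVarianceError(ValueError):
    """Raised when scaling is asked of features with no variance."""

    def __init__(self, feature_ids: list[str]):
        self.feature_ids = feature_ids
        super().__init__(f"zero-variance features cannot be scaled: {feature_ids}")


def uv_scale(table: FeatureTable, center: bool = False) -> FeatureTable:
    """Divide each feature by its sample (n−1) standard deviation.

    With ``center=True`` the mean is also removed (conventional UV/autoscaling);
    the default divides only, so already-unit-sd columns pass through unchanged
    and the operation is idempotent.  The input table is not modified.
    """
    x = table.intensities
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ZeroVarianceError([table.feature_ids[j] for j in zero])
    scaled = x / sd
    if center:
        scaled = scaled - scaled.mean(axis=0)
    return FeatureTable(
        list(table.sample_ids), list(table.feature_ids), scaled, table.labels.copy()
    )


def is_unit_scaled(table: FeatureTable, tol: float = 1e-6) -> bool:
    """True when every column's sample sd is within ``tol`` of 1."""
    sd = table.intensities.std(axis=0, ddof=1)
    return bool(np.all(np.abs(sd - 1.0) <= tol))
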