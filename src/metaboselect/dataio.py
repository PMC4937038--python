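"""Readers and writers for the pipeline's interchange formats.

The central in-memory container is :class:`FeatureTable`, a samples×features
intensity matrix with sample identifiers, feature identifiers (typically
``"m/z 145"``-style labels) and a binary class label per sample (``+1`` = Case,
``-1`` = Control).  Tables are exchanged as delimited text (one row per sample,
one column per feature); formal contexts use the Burmeister ``.cxt`` dialect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("metaboselect")

#: Canonical serialized class labels.  The Control label is written with the
#: Unicode minus sign; the ASCII hyphen-minus form is accepted on read.
CASE_LABEL = "1"
CONTROL_LABEL = "−1"

_LABEL_MAP = {
    "1": 1,
    "+1": 1,
    "−1": -1,
    "-1": -1,
}


class FeatureTableError(ValueError):
    """Raised for malformed feature tables (I/O or construction)."""


@dataclass
class FeatureTable:
    """Samples×features intensity matrix with binary class labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    feature_ids : sequence of str
        Unique feature identifiers, one per column.
    intensities : ndarray of shape (n_samples, n_features)
        Real-valued intensities; no missing values allowed.
    labels : ndarray of shape (n_samples,)
        Integer class labels, ``+1`` (Case) or ``-1`` (Control).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    intensities: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.intensities.shape
        if len(self.sample_ids) != n:
            raise FeatureTableError(
                f"{len(self.sample_ids)} sample ids for {n} intensity rows"
            )
        if len(self.feature_ids) != p:
            raise FeatureTableError(
                f"{len(self.feature_ids)} feature ids for {p} intensity columns"
            )
        if len(set(self.sample_ids)) != n:
            raise FeatureTableError("duplicated sample ids")
        if len(set(self.feature_ids)) != p:
            dupes = _duplicates(self.feature_ids)
            raise FeatureTableError(f"duplicated feature ids: {dupes}")
        if self.labels.shape != (n,):
            raise FeatureTableError("labels must be one per sample")
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise FeatureTableError(f"labels must be +1/-1; found {sorted(bad)}")
        if not np.all(np.isfinite(self.intensities)):
            r, c = np.argwhere(~np.isfinite(self.intensities))[0]
            raise FeatureTableError(
                f"non-finite intensity at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes_present(self) -> set[int]:
        return set(np.unique(self.labels))

    def require_both_classes(self) -> None:
        if self.classes_present != {1, -1}:
            raise FeatureTableError(
                f"both classes required; present: {sorted(self.classes_present)}"
            )

    def column(self, feature_id: str) -> np.ndarray:
        return self.intensities[:, self.feature_ids.index(feature_id)]

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (in that order)."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise FeatureTableError(f"unknown feature ids: {missing}")
        cols = [index[f] for f in feature_ids]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            intensities=self.intensities[:, cols].copy(),
            labels=self.labels.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, index=self.sample_ids, columns=self.feature_ids
        )
        df.insert(0, "class", [format_label(v) for v in self.labels])
        df.index.name = "sample_id"
        return df

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.sample_ids),
            list(self.feature_ids),
            self.intensities.copy(),
            self.labels.copy(),
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def format_label(value: int) -> str:
    return CASE_LABEL if value == 1 else CONTROL_LABEL


def parse_label(text: str, sample_id: str = "?") -> int:
    try:
        return _LABEL_MAP[text.strip()]
    except KeyError:
        raise FeatureTableError(
            f"sample {sample_id!r}: invalid class label {text!r} "
            f"(expected '1' or '−1')"
        ) from None


# ----------------------------------------------------------------------
# Feature-table text I/O
# ----------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write ``table`` as delimited text.

    Layout: header ``sample_id<delim>class<delim><feature ids...>``, then one
    row per sample.  Floats are written with ``repr`` so finite decimal values
    round-trip bit-identically.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["sample_id", "class", *table.feature_ids]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            cells = [sid, format_label(table.labels[i])]
            cells.extend(repr(float(v)) for v in table.intensities[i])
            fh.write(delimiter.join(cells) + "\n")


def read_feature_table(path: str | Path, delimiter: str = "\t") -> FeatureTable:
    """Read a delimited feature table written by :func:`write_feature_table`.

    Rejects duplicated feature ids, missing or invalid labels, and
    non-numeric cells with row/column diagnostics.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FeatureTableError(f"{path}: empty file")
        cols = header.rstrip("\n").split(delimiter)
        if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "class":
            raise FeatureTableError(
                f"{path}: header must start with 'sample_id{delimiter}class'"
            )
        feature_ids = cols[2:]
        dupes = _duplicates(feature_ids)
        if dupes:
            raise FeatureTableError(f"{path}: duplicated feature ids: {dupes}")
        sample_ids: list[str] = []
        labels: list[int] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(delimiter)
            if len(cells) != len(cols):
                raise FeatureTableError(
                    f"{path}:{lineno}: expected {len(cols)} cells, got {len(cells)}"
                )
            sid = cells[0]
            if not cells[1].strip():
                raise FeatureTableError(f"{path}:{lineno}: missing label for sample {sid!r}")
            labels.append(parse_label(cells[1], sample_id=sid))
            values = []
            for j, cell in enumerate(cells[2:]):
                try:
                    values.append(float(cell))
                except ValueError:
                    raise FeatureTableError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in "
                        f"feature column {feature_ids[j]!r}"
                    ) from None
            sample_ids.append(sid)
            rows.append(values)
    if not rows:
        raise FeatureTableError(f"{path}: no sample rows")
    return FeatureTable(sample_ids, feature_ids, np.array(rows, dtype=float), np.array(labels))


# ----------------------------------------------------------------------
# Burmeister .cxt formal-context I/O
# ----------------------------------------------------------------------

class CxtError(ValueError):
    """Raised for malformed ``.cxt`` files (message carries the line number)."""


def write_cxt(context, path: str | Path) -> None:
    """Write a formal context in the Burmeister ``.cxt`` dialect.

    Layout: line ``B``, blank line, object count, attribute count, blank
    line, object names, attribute names, then one ``X``/``.`` row per object.
    """
    objects = list(context.objects)
    attributes = list(context.attributes)
    incidence = np.asarray(context.incidence, dtype=int)
    if len(objects) == 0 or len(attributes) == 0:
        raise CxtError("refusing to write an empty context")
    lines = ["B", "", str(len(objects)), str(len(attributes)), ""]
    lines.extend(objects)
    lines.extend(attributes)
    for row in incidence:
        lines.append("".join("X" if v else "." for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cxt(path: str | Path):
    """Read a Burmeister ``.cxt`` file; inverse of :func:`write_cxt`."""
    from .stability import FormalContext  # local import to avoid a cycle

    raw = Path(path).read_text(encoding="utf-8").splitlines()
    if not raw or raw[0].strip() != "B":
        raise CxtError(f"{path}:1: expected format marker 'B'")
    # tolerate the conventional blank lines after "B" and after the counts
    idx = 1
    while idx < len(raw) and not raw[idx].strip():
        idx += 1
    try:
        n_obj = int(raw[idx])
        n_attr = int(raw[idx + 1])
    except (IndexError, ValueError):
        raise CxtError(f"{path}:{idx + 1}: malformed object/attribute counts") from None
    idx += 2
    while idx < len(raw) and not raw[idx].strip():
        idx += 1
    names = raw[idx : idx + n_obj + n_attr]
    if len(names) < n_obj + n_attr:
        raise CxtError(f"{path}:{idx + 1}: expected {n_obj + n_attr} name lines")
    objects = names[:n_obj]
    attributes = names[n_obj : n_obj + n_attr]
    body_start = idx + n_obj + n_attr
    body = raw[body_start : body_start + n_obj]
    if len(body) < n_obj:
        raise CxtError(f"{path}:{body_start + 1}: expected {n_obj} incidence rows")
    incidence = np.zeros((n_obj, n_attr), dtype=int)
    for i, line in enumerate(body):
        if len(line) != n_attr:
            raise CxtError(
                f"{path}:{body_start + i + 1}: incidence row has {len(line)} "
                f"characters, expected {n_attr}"
            )
        for j, ch in enumerate(line):
            if ch == "X":
                incidence[i, j] = 1
            elif ch != ".":
                raise CxtError(
                    f"{path}:{body_start + i + 1}: invalid incidence character {ch!r}"
                )
    return FormalContext(objects=objects, attributes=attributes, incidence=incidence)


# ----------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Workflow constants: filter thresholds, top-n sizes, model parameters.

    Defaults are the study's operating point: Pearson redundancy cut at 0.95,
    average-mutual-information cut at 0.02 nats, top-200 lists for filtered
    routes and top-178 for unfiltered ones, ANOVA entry at p<0.1, 2000-tree
    forests with mtry = 2·⌈√p⌉, consensus over ≥6 of the ten techniques, and
    the logistic pipeline's 0.25 entry p-value and 0.5 collinearity ceiling.
    """

    correlation_threshold: float = 0.95
    mi_threshold: float = 0.02
    consensus_k: int = 6
    anova_p: float = 0.1
    logistic_entry_p: float = 0.25
    logistic_max_r: float = 0.5
    logistic_shortlist: int = 10
    top_n_filtered: int = 200
    top_n_unfiltered: int = 178
    n_trees: int = 2000
    mtry_factor: float = 2.0
    selection_replicates: int = 50
    prediction_replications: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.mi_threshold < 0:
            raise ValueError("mi_threshold must be non-negative")
        for name in (
            "consensus_k",
            "logistic_shortlist",
            "top_n_filtered",
            "top_n_unfiltered",
            "n_trees",
            "selection_replicates",
            "prediction_replications",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("anova_p", "logistic_entry_p", "logistic_max_r"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain-text ``key: value`` configuration file."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key, value = (part.strip() for part in line.split(":", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            caster = int if known[key] in ("int", int) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def log_run(config: RunConfig, stage: str, **shapes) -> None:
    """Log one pipeline stage: config hash, seed, and named shapes/counts."""
    details = ", ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s config=%s seed=%d %s", stage, config.digest(), config.seed, details)
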