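"""Softmax scoring front-end and score-vector CSV I/O.

A *score vector* is a softmax output: non-negative class probabilities
summing to one.  In the four-class brain-tumor task the components follow
the label coding 0 = no tumor, 1 = meningioma, 2 = pituitary tumor,
3 = glioma.  Datasets travel as plain CSV with header ``s0,...,s{K-1},label``
(comma-separated, '.' decimal, UTF-8, no index column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "ScoreParseError",
    "ScoreValidationError",
    "validate_scores",
    "softmax",
    "LabelledDataset",
    "load_scores",
    "save_scores",
]

DEFAULT_CLASS_NAMES = ("no tumor", "meningioma", "pituitary tumor", "glioma")

#: Allowed deviation of a score vector's sum from 1.
SUM_ATOL = 1e-8


class ScoreParseError(ValueError):
    """A CSV row or header could not be parsed."""


class ScoreValidationError(ValueError):
    """A parsed value violates score-vector or label invariants."""


def validate_scores(scores: np.ndarray, row: int | None = None) -> np.ndarray:
    """Check one score vector: entries in [0, 1], summing to 1 within 1e-8."""
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    where = f" (row {row})" if row is not None else ""
    if scores.size < 2:
        raise ScoreValidationError(f"score vector needs >= 2 entries{where}")
    if not np.all(np.isfinite(scores)):
        raise ScoreValidationError(f"non-finite score{where}")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ScoreValidationError(f"score outside [0, 1]{where}: {scores.tolist()}")
    total = scores.sum()
    if abs(total - 1.0) > SUM_ATOL:
        raise ScoreValidationError(f"scores sum to {total!r}, not 1{where}")
    return scores


def softmax(logits) -> np.ndarray:
    """Numerically stable softmax: exp(z_i - max z) / sum_j exp(z_j - max z).

    Invariant to adding a constant to all logits; output is a valid score
    vector summing to 1 within 1e-12.
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    if z.size < 2:
        raise ValueError("softmax needs at least 2 logits")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    e = np.exp(z - z.max())
    return e / e.sum()


def _default_names(n_classes: int) -> tuple[str, ...]:
    if n_classes == len(DEFAULT_CLASS_NAMES):
        return DEFAULT_CLASS_NAMES
    return tuple(f"class {c}" for c in range(n_classes))


@dataclass(frozen=True)
class LabelledDataset:
    """Score vectors with integer labels, stored column-wise.

    ``scores`` is (N, K) float64, one validated score vector per row;
    ``labels`` is (N,) int64 with values in [0, K).
    """

    scores: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if scores.shape[0] != labels.shape[0]:
            raise ValueError("scores and labels differ in length")
        k = scores.shape[1]
        names = tuple(self.class_names) or _default_names(k)
        object.__setattr__(self, "class_names", names)
        if len(names) != k:
            raise ValueError(f"{len(names)} class names for {k} classes")
        if labels.size and (labels.min() < 0 or labels.max() >= k):
            raise ScoreValidationError(f"labels must lie in [0, {k})")

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(self.scores[idx], self.labels[idx], self.class_names)


def load_scores(path: str | Path, class_names: tuple[str, ...] = ()) -> LabelledDataset:
    """Read a labelled score CSV, rejecting invalid rows by row number.

    Row numbers in error messages count data rows from 1 (the header is
    row 0).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ScoreParseError(f"{path}: {exc}") from exc
    cols = list(frame.columns)
    k = len(cols) - 1
    expected = [f"s{i}" for i in range(k)] + ["label"]
    if k < 2 or cols != expected:
        raise ScoreParseError(f"{path}: expected header {','.join(expected) if k >= 2 else 's0,...,label'}, got {','.join(cols)}")
    scores = np.empty((len(frame), k))
    labels = np.empty(len(frame), dtype=np.int64)
    for i in range(len(frame)):
        row = i + 1
        try:
            vec = frame.iloc[i, :k].to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise ScoreParseError(f"{path}: row {row}: cannot parse scores ({exc})") from exc
        raw_label = frame.iloc[i, k]
        try:
            label = int(raw_label)
        except (TypeError, ValueError) as exc:
            raise ScoreParseError(f"{path}: row {row}: label {raw_label!r} is not an integer") from exc
        scores[i] = validate_scores(vec, row=row)
        if not 0 <= label < k:
            raise ScoreValidationError(f"{path}: row {row}: label {label} outside [0, {k})")
        labels[i] = label
    return LabelledDataset(scores, labels, class_names or _default_names(k))


def save_scores(dataset: LabelledDataset, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`load_scores` (17 significant digits)."""
    k = dataset.n_classes
    frame = pd.DataFrame(
        {f"s{i}": dataset.scores[:, i] for i in range(k)} | {"label": dataset.labels}
    )
    frame.to_csv(path, index=False, float_format="%.17g")
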