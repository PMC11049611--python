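"""The p16-CD8-Ki67 triple score: three ordinal bin scales, a 0-10 composite
total, and the total >= 9 positivity rule for CDKN2A homozygous deletion.

The rubric maps each marker percentage onto an ordinal sub-score so that
higher values accumulate for the phenotype associated with homozygous CDKN2A
loss: low/absent p16 expression, depleted CD8+ peritumoral TILs and a high
Ki67 proliferation index.

====================  =========  =========  =========  =====  =======
marker                score 0    score 1    score 2    sc. 3  sc. 4
====================  =========  =========  =========  =====  =======
p16 positive cells    51-100%    11-50%     1-10%      0%     --
CD8+ peritumoral TIL  61-100%    20-60%     1-19%      0%     --
Ki67 index            0-1%       2-5%       6-10%      11-20% 21-100%
====================  =========  =========  =========  =====  =======

All scales are defined on the integer percent grid 0..100 (inputs are rounded
half-up on ingest); the closed integer ranges resolve the boundary ambiguity
of the prose classes ("<20%" vs "0%", "2-5" vs "6-10") and reproduce the
reference cohort's published totals.  The composite total is the plain sum,
range 0-10, and a tumour is called positive for homozygous deletion when the
total reaches the detection threshold, 9 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort_io import Cohort, PatientRecord

__all__ = [
    "ScoreRubric",
    "DEFAULT_RUBRIC",
    "ScoreBreakdown",
    "Classification",
    "TripleScoreClassifier",
    "score_p16",
    "score_cd8",
    "score_ki67",
    "compute_triple_score",
    "classify",
    "score_cohort",
]

Bins = tuple[tuple[int, int, int], ...]  # (low, high, score), closed ranges

_P16_BINS: Bins = ((0, 0, 3), (1, 10, 2), (11, 50, 1), (51, 100, 0))
_CD8_BINS: Bins = ((0, 0, 3), (1, 19, 2), (20, 60, 1), (61, 100, 0))
_KI67_BINS: Bins = ((0, 1, 0), (2, 5, 1), (6, 10, 2), (11, 20, 3), (21, 100, 4))


def _lookup_table(bins: Bins) -> np.ndarray:
    table = np.full(101, -1, dtype=np.int64)
    for low, high, score in bins:
        table[low : high + 1] = score
    if (table < 0).any():
        raise ValueError("bins do not cover 0..100")
    return table


@dataclass(frozen=True)
class ScoreRubric:
    """The three bin scales as closed integer ranges on 0..100.

    The default rubric is a fixed constant of the method; alternative bins
    can be supplied for sensitivity analysis only.  Each scale must cover
    0..100 exactly (no gaps, no overlaps).
    """

    p16_bins: Bins = _P16_BINS
    cd8_bins: Bins = _CD8_BINS
    ki67_bins: Bins = _KI67_BINS

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            _lookup_table(self.p16_bins),
            _lookup_table(self.cd8_bins),
            _lookup_table(self.ki67_bins),
        )

    @property
    def max_total(self) -> int:
        return sum(
            max(score for _, _, score in bins)
            for bins in (self.p16_bins, self.cd8_bins, self.ki67_bins)
        )


DEFAULT_RUBRIC = ScoreRubric()
_P16_TABLE, _CD8_TABLE, _KI67_TABLE = DEFAULT_RUBRIC.tables()


@dataclass(frozen=True)
class ScoreBreakdown:
    """The three ordinal sub-scores and their composite total."""

    p16_score: int
    cd8_score: int
    ki67_score: int

    @property
    def total(self) -> int:
        return self.p16_score + self.cd8_score + self.ki67_score


@dataclass(frozen=True)
class Classification:
    """Positivity call of one score total at a detection threshold."""

    predicted_positive: bool
    threshold: int = 9


def _check_percent(value: int, marker: str) -> int:
    value = int(value)
    if not 0 <= value <= 100:
        raise ValueError(f"{marker} percentage {value} outside [0, 100]")
    return value


def score_p16(p16_pct: int) -> int:
    """Sub-score for the percentage of p16-positive tumour cells (0-3)."""
    return int(_P16_TABLE[_check_percent(p16_pct, "p16")])


def score_cd8(cd8_pct: int) -> int:
    """Sub-score for the percentage of CD8+ peritumoral TILs (0-3)."""
    return int(_CD8_TABLE[_check_percent(cd8_pct, "CD8")])


def score_ki67(ki67_pct: int) -> int:
    """Sub-score for the Ki67 proliferation index (0-4)."""
    return int(_KI67_TABLE[_check_percent(ki67_pct, "Ki67")])


def compute_triple_score(record: PatientRecord) -> ScoreBreakdown:
    """Score one patient record with the default rubric."""
    return ScoreBreakdown(
        p16_score=score_p16(record.p16_pct),
        cd8_score=score_cd8(record.cd8_pct),
        ki67_score=score_ki67(record.ki67_pct),
    )


def classify(breakdown: ScoreBreakdown, threshold: int = 9) -> Classification:
    """Call a tumour positive for homozygous deletion iff total >= threshold."""
    threshold = int(threshold)
    if not 0 <= threshold <= 10:
        raise ValueError(f"threshold {threshold} outside [0, 10]")
    return Classification(
        predicted_positive=breakdown.total >= threshold, threshold=threshold
    )


class TripleScoreClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier applying the triple-score rubric.

    The rubric is a fixed constant of the method, so :meth:`fit` only
    validates the input and freezes the rubric; no parameter is learned.
    The estimator composes with scikit-learn pipelines and model selection
    (e.g. a grid search over ``threshold``).

    Parameters
    ----------
    threshold : int, default 9
        Minimum composite total called positive, in [0, 10].
    rubric : ScoreRubric or None, default None
        Alternative bin scales for sensitivity analysis; ``None`` selects the
        standard rubric.

    Attributes
    ----------
    rubric_ : ScoreRubric
        The rubric frozen at fit time.
    classes_ : ndarray of shape (2,)
        ``[False, True]`` (positive = predicted homozygous deletion).

    Examples
    --------
    >>> clf = TripleScoreClassifier().fit([[0, 0, 40]])
    >>> clf.predict([[0, 0, 40], [50, 70, 60]])
    array([ True, False])
    """

    def __init__(self, threshold: int = 9, rubric: ScoreRubric | None = None):
        self.threshold = threshold
        self.rubric = rubric

    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = ["p16_pct", "cd8_pct", "ki67_pct"]
            if all(c in X.columns for c in cols):
                X = X[cols]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must have three columns: p16_pct, cd8_pct, ki67_pct"
            )
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        X = np.floor(X + 0.5).astype(np.int64)  # half-up onto the integer grid
        if ((X < 0) | (X > 100)).any():
            raise ValueError("marker percentages must lie in [0, 100]")
        return X

    def fit(self, X, y=None) -> "TripleScoreClassifier":
        """Validate ``X`` and freeze the rubric; ``y`` is ignored."""
        X = self._validate_X(X)
        rubric = self.rubric if self.rubric is not None else DEFAULT_RUBRIC
        if not 0 <= int(self.threshold) <= rubric.max_total:
            raise ValueError(
                f"threshold {self.threshold} outside [0, {rubric.max_total}]"
            )
        self.rubric_ = rubric
        self._tables_ = rubric.tables()
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        """Sub-scores and total, shape (n, 4): p16, CD8, Ki67, total."""
        self._check_fitted()
        X = self._validate_X(X)
        p16_t, cd8_t, ki67_t = self._tables_
        sub = np.column_stack(
            [p16_t[X[:, 0]], cd8_t[X[:, 1]], ki67_t[X[:, 2]]]
        )
        return np.column_stack([sub, sub.sum(axis=1)])

    def decision_function(self, X) -> np.ndarray:
        """Signed margin ``total - threshold``; >= 0 means positive."""
        return self.transform(X)[:, 3] - int(self.threshold)

    def predict(self, X) -> np.ndarray:
        """Boolean homozygous-deletion call per row."""
        return self.decision_function(X) >= 0

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "rubric_"):
            raise AttributeError(
                "This TripleScoreClassifier instance is not fitted yet; "
                "call 'fit' first."
            )


def score_cohort(cohort: Cohort, threshold: int = 9) -> pd.DataFrame:
    """Score every record of a cohort.

    Returns a frame with one row per record in input order and columns
    ``patient_id, p16_score, cd8_score, ki67_score, total,
    predicted_positive, cdkn2a, split``.
    """
    if not 0 <= int(threshold) <= 10:
        raise ValueError(f"threshold {threshold} outside [0, 10]")
    rows = []
    for record in cohort:
        breakdown = compute_triple_score(record)
        rows.append(
            {
                "patient_id": record.patient_id,
                "p16_score": breakdown.p16_score,
                "cd8_score": breakdown.cd8_score,
                "ki67_score": breakdown.ki67_score,
                "total": breakdown.total,
                "predicted_positive": classify(breakdown, threshold).predicted_positive,
                "cdkn2a": record.cdkn2a.value,
                "split": record.split.value,
            }
        )
    columns = [
        "patient_id",
        "p16_score",
        "cd8_score",
        "ki67_score",
        "total",
        "predicted_positive",
        "cdkn2a",
        "split",
    ]
    return pd.DataFrame(rows, columns=columns)
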