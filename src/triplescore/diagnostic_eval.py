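"""Diagnostic evaluation of the triple score against the FISH ground truth.

Covers the 2x2 confusion matrix at a chosen cut-off, sensitivity and
specificity, a full threshold sweep with the Youden index, per-group marker
means with Welch's unequal-variance t-test (the wild-type group pools disomy
and monosomy; the mutated group pools homo- and heterozygous deletions), and
percentile-bootstrap confidence intervals for the accuracy metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cdkn2aStatus, Cohort

__all__ = [
    "ConfusionMatrix",
    "GroupComparison",
    "WelchResult",
    "confusion_matrix",
    "false_negative_heterozygous_count",
    "group_means",
    "welch_t_test",
    "threshold_sweep",
    "bootstrap_ci",
    "evaluation_report",
    "display_mean",
]

MARKERS = ("p16", "cd8", "ki67")
POSITIVE_DEFINITIONS = ("homozygous_deletion", "any_mutation")

#: Caveats attached verbatim to every evaluation report.
REPORT_NOTES = (
    "Specificity uses the standard definition tn/(tn+fp); on the bundled "
    "cohort this is 15/16 = 93.75%. The originally reported 94.11% (= 16/17) "
    "is not recoverable from 16 negatives under any standard denominator.",
    "The originally reported CD8 p-value (0.1185) is not reproduced by "
    "Welch's test (~0.108) or the pooled-variance t-test (~0.142) on the "
    "bundled marker values.",
)


def display_mean(value: float) -> float:
    """Truncate a percentage mean to 2 decimals for display.

    Internal comparisons always use full precision; truncation (not
    rounding) is the display convention the reference results follow
    (e.g. 550/13 = 42.3077 is shown as 42.30).
    """
    return math.floor(float(value) * 100) / 100


def _truth_mask(cdkn2a: pd.Series, positive_definition: str) -> np.ndarray:
    if positive_definition not in POSITIVE_DEFINITIONS:
        raise ValueError(
            f"positive_definition must be one of {POSITIVE_DEFINITIONS}"
        )
    statuses = cdkn2a.map(Cdkn2aStatus)
    if positive_definition == "homozygous_deletion":
        return np.asarray([s.is_homozygous for s in statuses])
    return np.asarray([s.is_mutated for s in statuses])


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of score positivity against the FISH label."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: int = 9
    positive_definition: str = "homozygous_deletion"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        """True-positive rate tp/(tp+fn); undefined without true positives."""
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("sensitivity undefined: no positive cases")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """True-negative rate tn/(tn+fp); undefined without true negatives."""
        if self.tn + self.fp == 0:
            raise ZeroDivisionError("specificity undefined: no negative cases")
        return self.tn / (self.tn + self.fp)


class WelchResult(NamedTuple):
    t_statistic: float
    welch_df: float
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    """Wild-type vs mutated group means of one marker, with Welch statistics."""

    marker: str
    mean_wt: float
    mean_mut: float
    n_wt: int
    n_mut: int
    t_statistic: float
    welch_df: float
    p_value: float


def confusion_matrix(
    scored: pd.DataFrame,
    positive_definition: str = "homozygous_deletion",
    threshold: int = 9,
) -> ConfusionMatrix:
    """Tally score calls at ``threshold`` against the CDKN2A labels.

    ``scored`` is the output of :func:`triplescore.score_cohort`; predictions
    are re-derived from the ``total`` column so one scored frame supports any
    cut-off.
    """
    if len(scored) == 0:
        raise ValueError("cannot evaluate an empty scored cohort")
    if not 0 <= int(threshold) <= 10:
        raise ValueError(f"threshold {threshold} outside [0, 10]")
    truth = _truth_mask(scored["cdkn2a"], positive_definition)
    predicted = scored["total"].to_numpy() >= int(threshold)
    return ConfusionMatrix(
        tp=int((truth & predicted).sum()),
        fp=int((~truth & predicted).sum()),
        tn=int((~truth & ~predicted).sum()),
        fn=int((truth & ~predicted).sum()),
        threshold=int(threshold),
        positive_definition=positive_definition,
    )


def false_negative_heterozygous_count(
    scored: pd.DataFrame, threshold: int = 9
) -> int:
    """Heterozygous-deletion carriers scoring below the cut-off.

    These are the expected misses of a test targeting homozygous loss only.
    """
    if len(scored) == 0:
        raise ValueError("cannot evaluate an empty scored cohort")
    het = scored["cdkn2a"] == Cdkn2aStatus.HETEROZYGOUS_DELETION.value
    return int((het & (scored["total"] < int(threshold))).sum())


def welch_t_test(
    x: Iterable[float], y: Iterable[float], tails: int = 2
) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Degenerate inputs (fewer than two observations per sample, or two
    zero-variance samples) are rejected rather than returning NaN.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    result = stats.ttest_ind(x, y, equal_var=False)
    p_value = float(result.pvalue)
    if tails == 1:
        p_value /= 2.0
    return WelchResult(
        t_statistic=float(result.statistic),
        welch_df=float(result.df),
        p_value=p_value,
    )


def group_means(cohort: Cohort, marker: str) -> GroupComparison:
    """Per-group arithmetic means of one marker with Welch statistics.

    Groups follow the copy-number dichotomy: wild type pools disomy and
    monosomy; mutated pools homo- and heterozygous deletions.
    """
    if marker not in MARKERS:
        raise ValueError(f"marker must be one of {MARKERS}")
    attr = f"{marker}_pct"
    wt = [getattr(r, attr) for r in cohort if not r.cdkn2a.is_mutated]
    mut = [getattr(r, attr) for r in cohort if r.cdkn2a.is_mutated]
    if not wt or not mut:
        raise ValueError("both the wild-type and mutated groups must be non-empty")
    welch = welch_t_test(wt, mut)
    return GroupComparison(
        marker=marker,
        mean_wt=float(np.mean(wt)),
        mean_mut=float(np.mean(mut)),
        n_wt=len(wt),
        n_mut=len(mut),
        t_statistic=welch.t_statistic,
        welch_df=welch.welch_df,
        p_value=welch.p_value,
    )


def threshold_sweep(
    scored: pd.DataFrame, positive_definition: str = "homozygous_deletion"
) -> pd.DataFrame:
    """Sensitivity, specificity and Youden index at every cut-off 0..10.

    Because positivity is ``total >= threshold``, sensitivity is
    non-increasing and specificity non-decreasing in the threshold.
    """
    rows = []
    for threshold in range(11):
        cm = confusion_matrix(scored, positive_definition, threshold)
        sens = cm.sensitivity
        spec = cm.specificity
        rows.append(
            {
                "threshold": threshold,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sensitivity": sens,
                "specificity": spec,
                "youden": sens + spec - 1.0,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    scored: pd.DataFrame,
    metric: str = "sensitivity",
    n_boot: int = 2000,
    seed: int = 0,
    positive_definition: str = "homozygous_deletion",
    threshold: int = 9,
) -> tuple[float, float]:
    """Percentile (2.5/97.5) bootstrap interval for sensitivity or specificity.

    Patients are resampled with replacement; replicates in which the metric
    is undefined (no positive, resp. negative, cases drawn) are redrawn.  If
    more than half of the attempted replicates are undefined the cohort is
    too small to bootstrap and an error is raised.
    """
    if metric not in ("sensitivity", "specificity"):
        raise ValueError("metric must be 'sensitivity' or 'specificity'")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    truth = _truth_mask(scored["cdkn2a"], positive_definition)
    predicted = scored["total"].to_numpy() >= int(threshold)
    rng = np.random.default_rng(seed)
    n = len(scored)
    values: list[float] = []
    attempts = 0
    max_attempts = 2 * n_boot
    while len(values) < n_boot and attempts < max_attempts:
        idx = rng.integers(0, n, size=n)
        t, p = truth[idx], predicted[idx]
        attempts += 1
        if metric == "sensitivity":
            denom = t.sum()
            num = (t & p).sum()
        else:
            denom = (~t).sum()
            num = (~t & ~p).sum()
        if denom == 0:
            continue
        values.append(num / denom)
    if len(values) < n_boot:
        raise ValueError(
            f"{metric} undefined in more than half of the bootstrap "
            "replicates; the cohort is too small to bootstrap this metric"
        )
    lower, upper = np.percentile(values, [2.5, 97.5])
    return float(lower), float(upper)


def evaluation_report(
    cohort: Cohort,
    threshold: int = 9,
    positive_definition: str = "homozygous_deletion",
    n_boot: int | None = None,
    seed: int = 0,
) -> dict:
    """Full JSON-serialisable evaluation of a cohort.

    Contains the confusion matrix and accuracy metrics at ``threshold``, the
    full threshold sweep, the three per-marker group comparisons, optional
    bootstrap intervals, and standing caveats about the reference cohort.
    """
    from .triple_score import score_cohort  # local import avoids a cycle

    scored = score_cohort(cohort, threshold=threshold)
    cm = confusion_matrix(scored, positive_definition, threshold)
    sweep = threshold_sweep(scored, positive_definition)
    report = {
        "cohort": cohort.name,
        "n": len(cohort),
        "threshold": int(threshold),
        "positive_definition": positive_definition,
        "counts": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "sensitivity_pct_display": round(100 * cm.sensitivity, 2),
        "specificity_pct_display": round(100 * cm.specificity, 2),
        "false_negative_heterozygous": false_negative_heterozygous_count(
            scored, threshold
        ),
        "sweep": sweep.to_dict(orient="records"),
        "group_comparisons": [
            {
                "marker": gc.marker,
                "mean_wt": gc.mean_wt,
                "mean_mut": gc.mean_mut,
                "mean_wt_display": display_mean(gc.mean_wt),
                "mean_mut_display": display_mean(gc.mean_mut),
                "n_wt": gc.n_wt,
                "n_mut": gc.n_mut,
                "t_statistic": gc.t_statistic,
                "welch_df": gc.welch_df,
                "p_value": gc.p_value,
            }
            for gc in (group_means(cohort, m) for m in MARKERS)
        ],
        "notes": list(REPORT_NOTES),
    }
    if n_boot is not None:
        report["bootstrap"] = {
            "n_boot": int(n_boot),
            "seed": int(seed),
            "sensitivity_ci": bootstrap_ci(
                scored, "sensitivity", n_boot, seed, positive_definition, threshold
            ),
            "specificity_ci": bootstrap_ci(
                scored, "specificity", n_boot, seed, positive_definition, threshold
            ),
        }
    return report
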