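"""Evaluation machinery: confusion metrics, trial accuracy, ROC/AUC,
performance-group assignment and between-group one-way ANOVA.

Conventions
-----------
* Confusion counts are taken over per-icon inputs: each icon of each decoded
  trial contributes one binary decision (1 target, 5 non-targets per trial),
  which is the granularity at which sensitivity/precision are non-degenerate.
* The correct-classification rate ``(TP+TN)/total`` is the learning-curve
  quantity; the corresponding error is one minus it, and both are labelled
  explicitly in outputs.
* Group assignment: a subject is "H" when its trial-level ERP detection rate
  exceeds 50%; exactly 50% falls in "L" (boundary decision).
* Report tables round to 3 decimals, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .decoder import TrialDecision

__all__ = [
    "ConfusionCounts",
    "SubjectMetrics",
    "sensitivity",
    "precision",
    "f1_measure",
    "trial_accuracy",
    "eq_correct_rate",
    "roc_auc",
    "assign_group",
    "anova_oneway",
    "round3",
    "load_reported_cohort",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise ValueError("predicted and truth must align")
        return cls(tp=int(np.sum(predicted & truth)),
                   fp=int(np.sum(predicted & ~truth)),
                   tn=int(np.sum(~predicted & ~truth)),
                   fn=int(np.sum(~predicted & truth)))


@dataclass(frozen=True)
class SubjectMetrics:
    """One summary row per subject, mirroring the cohort report table."""

    subject_id: str
    group_label: str        # generative phenotype (H-like / L-like)
    group: str              # assigned performance group (H / L)
    detection_rate: float
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    auc: float
    psnr_db: float
    pet_s: float


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (FN + TP); NaN when no true positives exist to detect."""
    denom = c.fn + c.tp
    return c.tp / denom if denom else float("nan")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing was predicted positive."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else float("nan")


def f1_measure(sens: float, prec: float) -> float:
    """Harmonic mean 2*s*p/(s+p); NaN when s + p = 0."""
    if math.isnan(sens) or math.isnan(prec) or sens + prec == 0:
        return float("nan")
    return 2.0 * sens * prec / (sens + prec)


def trial_accuracy(decisions: list[TrialDecision]) -> float:
    """Fraction of trials whose selected icon equals the true target."""
    if not decisions:
        raise ValueError("trial_accuracy: no decisions")
    return sum(d.selected_icon == d.true_target for d in decisions) / len(decisions)


def eq_correct_rate(c: ConfusionCounts) -> float:
    """Correct-classification rate (TP+TN)/total — the learning-curve
    quantity; the reported error is ``1 -`` this value."""
    if c.total == 0:
        raise ValueError("eq_correct_rate: empty counts")
    return (c.tp + c.tn) / c.total


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equivalent to trapezoidal integration of sensitivity against
    1-specificity over all thresholds; tied scores earn half credit.
    Returns NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # mid-ranks implement the tie convention
    rank_sum = float(ranks[truth].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def assign_group(rate: float) -> str:
    """Performance group from the ERP detection rate, thresholded at 50%."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"detection rate {rate} outside [0, 1]")
    return "H" if rate > 0.5 else "L"


def anova_oneway(group_a, group_b) -> tuple[float, float]:
    """Classic equal-variance one-way ANOVA on two groups.

    Returns (F, p).  Degenerate case (zero variance everywhere, equal
    means) yields (0.0, 1.0).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("anova_oneway: each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (report-table convention)."""
    if math.isnan(x):
        return x
    return math.copysign(math.floor(abs(x) * 1000 + 0.5) / 1000, x)


def load_reported_cohort() -> pd.DataFrame:
    """Published per-subject decoding metrics of the 33-subject RSVP-speller
    cohort whose paradigm this package's simulator emulates.

    Columns: subject, group (H/L by ERP detection), accuracy, sensitivity,
    precision, f1, auc, psnr_db, pet_s.  Used as worked-example input for
    the metric identities and the cohort split; the raw EEG behind it was
    never deposited.
    """
    with resources.files("erpspeller.data").joinpath("reported_cohort.csv").open() as fh:
        return pd.read_csv(fh)
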