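"""Diagnostic performance metrics: 2×2 confusion summaries, ROC/AUC with a
bootstrap confidence interval, and the Wilcoxon rank-sum comparison of group
scores.

Score tables are plain pandas DataFrames with columns
``sample_id, score, predicted, true`` (``predicted``/``true`` hold class
labels).  AUC is computed as the normalized Mann–Whitney U statistic — the
probability that a random positive scores above a random negative, ties
counted one half — so it depends only on score ranks.  The 95% CI comes
from a seeded, class-stratified percentile bootstrap (default 2000
replicates); when the classes are perfectly separated every replicate has
AUC 1, and the interval degenerates to (1.00, 1.00).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import roc_curve

from .errors import EvaluationError
from .io import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["sample_id", "score", "predicted", "true"]

#: exact Wilcoxon enumeration is used up to this smaller-group size (no ties)
EXACT_WILCOXON_MAX_N = 12


def make_score_table(rows, true_labels=None) -> pd.DataFrame:
    """Build a score table from ``(sample_id, score, predicted)`` tuples.

    ``true_labels`` is an optional sample_id→label map; samples without a
    true label get NA.
    """
    df = pd.DataFrame(rows, columns=["sample_id", "score", "predicted"])
    if true_labels is not None:
        df["true"] = df["sample_id"].map(true_labels)
    else:
        df["true"] = pd.NA
    return df


@dataclass(frozen=True)
class ConfusionSummary:
    """2×2 confusion counts with the five standard diagnostic ratios.

    Undefined ratios (zero denominator) are ``None`` — reported as
    not-available, never coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    def as_percent(self) -> dict[str, int | None]:
        """Whole-percent display rounding (internal values stay exact)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(100 * v)
        return out

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def confusion_metrics(
    scores: pd.DataFrame,
    positive_label: str = POSITIVE,
    negative_label: str = NEGATIVE,
) -> ConfusionSummary:
    """Confusion counts and ratios of predicted vs true labels."""
    if scores["true"].isna().any():
        missing = scores.loc[scores["true"].isna(), "sample_id"].tolist()
        raise EvaluationError(f"samples without true label: {missing}")
    pred = scores["predicted"].to_numpy()
    true = scores["true"].to_numpy()
    tp = int(np.sum((pred == positive_label) & (true == positive_label)))
    fp = int(np.sum((pred == positive_label) & (true == negative_label)))
    tn = int(np.sum((pred == negative_label) & (true == negative_label)))
    fn = int(np.sum((pred == negative_label) & (true == positive_label)))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class ROCResult:
    """AUC with a bootstrap 95% CI and the ROC curve coordinates."""

    auc: float
    ci_lo: float
    ci_hi: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC: P(pos > neg) + ½ P(pos == neg), via midranks."""
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_auc(
    scores: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    positive_label: str = POSITIVE,
) -> ROCResult:
    """ROC curve and AUC with a stratified percentile-bootstrap 95% CI.

    Bootstrap replicates resample positives and negatives separately (with
    replacement), seeded; the interval is the (2.5, 97.5) percentile span.
    """
    if scores["true"].isna().any():
        raise EvaluationError("all scored samples need a true label for ROC")
    y = (scores["true"].to_numpy() == positive_label).astype(int)
    s = scores["score"].to_numpy(float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("ROC needs both classes among the true labels")
    if n_boot < 1:
        raise EvaluationError(f"n_boot must be >= 1, got {n_boot}")

    auc = _auc_rank(pos, neg)
    fpr, tpr, thr = roc_curve(y, s)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = _auc_rank(bp, bn)
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    return ROCResult(
        auc=auc, ci_lo=float(ci_lo), ci_hi=float(ci_hi),
        fpr=fpr, tpr=tpr, thresholds=thr,
    )


def wilcoxon_rank_sum(
    scores_a, scores_b, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test of two score groups.

    Uses the exact null distribution (full enumeration) when the smaller
    group has ≤ 12 observations and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction (no continuity
    correction, so identical groups give p = 1 exactly).  Returns
    ``(U statistic of group a, two-sided p-value)``; significance at the
    conventional two-sided 0.05 level is logged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EvaluationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a), len(b)) <= EXACT_WILCOXON_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=False)
    p = float(min(res.pvalue, 1.0))
    logger.info(
        "wilcoxon rank-sum (%s): U=%g p=%g (%ssignificant at alpha=%g)",
        method, res.statistic, p, "" if p < alpha else "not ", alpha,
    )
    return float(res.statistic), p


def label_counts(scores: pd.DataFrame) -> dict[str, int]:
    return scores["true"].value_counts().to_dict()


def summarize(
    scores: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    positive_label: str = POSITIVE,
    negative_label: str = NEGATIVE,
) -> dict:
    """Confusion metrics + ROC/AUC + Wilcoxon p in one JSON-ready dict."""
    cm = confusion_metrics(scores, positive_label, negative_label)
    roc = roc_auc(scores, n_boot=n_boot, seed=seed, positive_label=positive_label)
    s = scores["score"].to_numpy(float)
    y = scores["true"].to_numpy()
    _, p = wilcoxon_rank_sum(s[y == negative_label], s[y == positive_label])
    return {
        "confusion": cm.as_dict(),
        "metrics_percent": cm.as_percent(),
        "auc": roc.auc,
        "auc_ci": [roc.ci_lo, roc.ci_hi],
        "wilcoxon_p": p,
        "n": int(len(scores)),
    }


def auc_from_scores(neg: np.ndarray, pos: np.ndarray) -> float:
    """Convenience rank-based AUC from raw per-class score arrays."""
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("AUC needs both classes")
    if math.isnan(np.sum(pos) + np.sum(neg)):
        raise EvaluationError("scores contain NaN")
    return _auc_rank(np.asarray(pos, float), np.asarray(neg, float))
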