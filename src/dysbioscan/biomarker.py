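"""Rank-order lysophospholipid scoring with ROC analysis and the
full-specificity cutoff.

Each panel species is ranked across the N subjects (1 = lowest fecal
concentration, N = highest, ties mid-ranked) and the per-subject ranks are
summed into a total rank-order score.  The score's discrimination is
summarised by the Mann-Whitney AUC, and the operating point is the smallest
case score that exceeds every control score, i.e. the threshold with 100%
specificity and maximal sensitivity; case samples at or above it are the
"high outlier" subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .tables import LipidTable

__all__ = [
    "DEFAULT_PANEL",
    "RankScoreTable",
    "RocCurve",
    "CutoffResult",
    "RankOrderScorer",
    "rank_score",
    "roc_curve",
    "full_specificity_cutoff",
]

#: The five-species lysophospholipid panel scored in the CD cohort.
DEFAULT_PANEL = (
    "LysoPS 18:0",
    "LysoPS 18:1",
    "LysoPC 18:0",
    "LysoPC 18:1",
    "LysoPC 22:1",
)


@dataclass
class RankScoreTable:
    """Per-sample per-species ranks plus the total rank-order score."""

    ranks: pd.DataFrame  # samples x panel species, values in [1, N]
    total_score: pd.Series
    group_labels: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.ranks.index


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_p: float


@dataclass
class CutoffResult:
    cutoff: float
    specificity: float
    sensitivity: float
    outlier_ids: list


def rank_score(table: LipidTable, panel=DEFAULT_PANEL) -> RankScoreTable:
    """Rank each panel species 1..N across samples and sum into total scores.

    Ties receive mid-ranks, so every species' ranks sum to N(N+1)/2 exactly.
    """
    panel = list(panel)
    missing = [s for s in panel if s not in table.concentrations.columns]
    if missing:
        raise ValueError(f"panel species missing from table: {missing}")
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples to rank")
    conc = table.concentrations[panel]
    ranks = conc.rank(axis=0, method="average")
    total = ranks.sum(axis=1)
    total.name = "total_score"
    return RankScoreTable(ranks=ranks, total_score=total,
                          group_labels=table.group_labels)


def _mann_whitney_auc(case: np.ndarray, control: np.ndarray) -> float:
    """AUC as the pair statistic U/(n_case*n_control), ties counted 1/2."""
    wins = (case[:, None] > control[None, :]).sum()
    ties = (case[:, None] == control[None, :]).sum()
    return (wins + 0.5 * ties) / (case.size * control.size)


def roc_curve(scores, labels) -> RocCurve:
    """ROC of a higher-is-case score; AUC by pair counting.

    The P value tests AUC = 0.5 via the tie-corrected normal approximation of
    the Mann-Whitney statistic (two-sided).
    """
    scores = np.asarray(scores, dtype=float)
    case = _case_mask(labels)
    if case.all() or not case.any():
        raise ValueError("both classes must be present")
    cs, ct = scores[case], scores[~case]
    n1, n2 = cs.size, ct.size
    auc = _mann_whitney_auc(cs, ct)

    # tie-corrected variance of U under the null
    n = n1 + n2
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    u = auc * n1 * n2
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n1 * n2 / 2.0) / np.sqrt(var_u)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))

    thresholds = np.unique(scores)[::-1]
    sens = np.array([(cs >= t).mean() for t in thresholds])
    spec = np.array([(ct < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=float(auc), auc_p=p)


def full_specificity_cutoff(scores, labels) -> CutoffResult:
    """Smallest case score strictly above every control score.

    Samples scoring at or above the cutoff are the high outliers; on its
    training data the operating point always has specificity exactly 1.  When
    no case exceeds all controls the result is empty with sensitivity 0 and a
    cutoff just above the control maximum.
    """
    index = scores.index if isinstance(scores, pd.Series) else None
    scores = pd.Series(np.asarray(scores, dtype=float), index=index)
    case = _case_mask(labels)
    if case.all() or not case.any():
        raise ValueError("both classes must be present")
    cs, ct = scores[case], scores[~case]
    ctrl_max = ct.max()
    above = cs[cs > ctrl_max]
    if above.empty:
        eps = np.spacing(ctrl_max) if ctrl_max != 0 else np.finfo(float).eps
        return CutoffResult(cutoff=float(ctrl_max + eps), specificity=1.0,
                            sensitivity=0.0, outlier_ids=[])
    cutoff = float(above.min())
    outliers = cs[cs >= cutoff]
    return CutoffResult(
        cutoff=cutoff,
        specificity=1.0,
        sensitivity=len(outliers) / len(cs),
        outlier_ids=list(outliers.index),
    )


def _case_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return labels == "CD"
    return labels.astype(bool)


class RankOrderScorer(BaseEstimator):
    """Fit the rank-order scoring model on a labelled lipid cohort.

    ``fit`` ranks the panel species, sums per-subject totals, computes the
    ROC/AUC against the labels, and locks in the full-specificity cutoff.
    ``predict`` re-ranks a (full) cohort table and flags samples at or above
    the fitted cutoff — the score is a within-cohort rank statistic, so
    prediction operates on whole cohorts, not single samples.
    """

    def __init__(self, panel=DEFAULT_PANEL):
        self.panel = panel

    def fit(self, X: LipidTable, y=None):
        score_table = rank_score(X, self.panel)
        labels = y if y is not None else X.group_labels
        self.score_table_ = score_table
        self.roc_ = roc_curve(score_table.total_score, labels)
        self.cutoff_result_ = full_specificity_cutoff(score_table.total_score, labels)
        self.cutoff_ = self.cutoff_result_.cutoff
        self.auc_ = self.roc_.auc
        self.outlier_ids_ = self.cutoff_result_.outlier_ids
        return self

    def decision_function(self, X: LipidTable) -> pd.Series:
        return rank_score(X, self.panel).total_score

    def predict(self, X: LipidTable) -> np.ndarray:
        return (self.decision_function(X) >= self.cutoff_).to_numpy()
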