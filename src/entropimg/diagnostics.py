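"""Correlation and diagnostic-performance statistics.

Pearson/Spearman correlations, empirical ROC analysis with the
Mann-Whitney AUROC estimator (ties counted 1/2), DeLong structural-component
standard errors, Youden-index cutoff selection with the full 2x2-table
metric set, and the paired DeLong test for comparing two correlated ROC
curves measured on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import ClassError, PairingError, ParameterError

__all__ = [
    "ROCResult",
    "pearson_r",
    "spearman_rs",
    "roc_analysis",
    "delong_test",
]

Direction = Literal["higher_is_positive", "lower_is_positive"]


def _corr_inputs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise PairingError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ParameterError("correlation needs at least 3 pairs")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN if either input is constant."""
    x, y = _corr_inputs(x, y)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rs(x, y) -> float:
    """Spearman rank correlation with average ranks for ties; NaN if constant."""
    x, y = _corr_inputs(x, y)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class ROCResult:
    """Empirical ROC summary at the Youden-optimal cutoff."""

    auroc: float
    se: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    n_pos: int
    n_neg: int
    direction: Direction = "higher_is_positive"
    fpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    tpr: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "auroc", "se", "cutoff", "sensitivity", "specificity",
                "accuracy", "ppv", "npv", "lr_pos", "lr_neg",
                "n_pos", "n_neg", "direction",
            )
        }
        d["roc_curve"] = {"fpr": self.fpr.tolist(), "tpr": self.tpr.tolist()}
        return d


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise PairingError(f"scores ({scores.size}) and labels ({labels.size}) differ")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ClassError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ClassError("both classes must be present")
    return scores, labels


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus the DeLong placement values V10 (per positive) and V01."""
    # placement of each positive among negatives, ties as 1/2
    v10 = np.empty(pos.size)
    for i, p in enumerate(pos):
        v10[i] = (np.count_nonzero(neg < p) + 0.5 * np.count_nonzero(neg == p)) / neg.size
    v01 = np.empty(neg.size)
    for j, q in enumerate(neg):
        v01[j] = (np.count_nonzero(pos > q) + 0.5 * np.count_nonzero(pos == q)) / pos.size
    return float(v10.mean()), v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def _empirical_roc(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, cutoffs); cutoffs are midpoints between adjacent uniques."""
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    tpr = np.array([(pos >= c).mean() for c in cutoffs])
    fpr = np.array([(neg >= c).mean() for c in cutoffs])
    return fpr, tpr, cutoffs


def roc_analysis(
    scores,
    labels,
    direction: Direction = "higher_is_positive",
    paired_scores=None,
) -> ROCResult:
    """Empirical ROC analysis with a Youden-optimal operating point.

    The AUROC is the Mann-Whitney concordance (ties 1/2); its standard error
    comes from the DeLong structural-component variance. The cutoff
    maximizes Youden's J = sensitivity + specificity - 1; ties are broken in
    favour of higher sensitivity. With ``direction='lower_is_positive'``
    (e.g. entropy falling with fibrosis severity) scores are negated
    internally and the cutoff is reported on the original scale with a
    "score <= cutoff is positive" reading.
    """
    scores, labels = _check_binary(scores, labels)
    flip = direction == "lower_is_positive"
    s = -scores if flip else scores
    pos, neg = s[labels == 1], s[labels == 0]
    auroc, v10, v01 = _structural_components(pos, neg)
    se = float(np.sqrt(_delong_variance(v10, v01)))

    fpr, tpr, cutoffs = _empirical_roc(pos, neg)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # ties in J: keep the highest sensitivity
    best = best[np.argmax(tpr[best])]
    cut = float(cutoffs[best])

    tp = int(np.count_nonzero(pos >= cut))
    fn = pos.size - tp
    fp = int(np.count_nonzero(neg >= cut))
    tn = neg.size - fp
    sens = tp / pos.size
    spec = tn / neg.size
    acc = (tp + tn) / scores.size
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else float("inf")

    order = np.lexsort((tpr, fpr))
    return ROCResult(
        auroc=auroc,
        se=se,
        cutoff=-cut if flip else cut,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        n_pos=pos.size,
        n_neg=neg.size,
        direction=direction,
        fpr=fpr[order],
        tpr=tpr[order],
    )


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test comparing two AUROCs on the same subjects.

    Returns ``(auc_a - auc_b, z, two-sided p)``. The variance of the
    difference uses the covariance of the structural components, which
    accounts for the pairing. Identical score vectors give (0, 0, 1).
    """
    scores_a = np.asarray(scores_a, dtype=float).ravel()
    scores_b = np.asarray(scores_b, dtype=float).ravel()
    if scores_a.size != scores_b.size:
        raise PairingError("paired score vectors must have equal length")
    _, labels = _check_binary(scores_a, labels)
    mask_pos = labels == 1
    auc_a, v10_a, v01_a = _structural_components(scores_a[mask_pos], scores_a[~mask_pos])
    auc_b, v10_b, v01_b = _structural_components(scores_b[mask_pos], scores_b[~mask_pos])
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = _delong_variance(d10, d01)
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(z), float(p)
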