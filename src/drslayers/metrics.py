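"""Evaluation metrics: MCC, rank-based AUC, Wilcoxon signed-rank, Bland-Altman."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["mcc", "auc", "wilcoxon_signed_rank", "bland_altman"]


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion-matrix counts.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``, defined as 0
    when any marginal is zero (e.g. all predictions in one class).
    """
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be non-negative with at least one prediction")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    The probability that a uniformly random positive outscores a uniformly
    random negative, with score ties counted one half. ``labels`` is boolean
    (True = positive class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def wilcoxon_signed_rank(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are removed first. With at most 25 remaining pairs and
    no tied absolute differences the exact null distribution is used;
    otherwise the normal approximation with tie correction. All differences
    zero yields p = 1 (with a warning).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 6:
        raise ValueError("paired 1-D samples of equal length >= 6 required")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    return float(
        stats.wilcoxon(d, alternative="two-sided", method=method, correction=False).pvalue
    )


def bland_altman(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Agreement summary: (bias, lower limit, upper limit).

    Bias is the mean of ``pred - truth``; the 95% limits of agreement are
    bias +/- 1.96 times the sample SD (n-1 denominator) of the differences.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or len(pred) < 2:
        raise ValueError("need paired arrays of equal length >= 2")
    d = pred - truth
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half
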