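"""Empirical ROC analysis with DeLong machinery and Youden operating points.

The empirical AUC is the normalized Mann–Whitney U statistic with midrank tie
handling; its variance and the covariance between two correlated AUCs come
from DeLong's structural components (the per-case placement values), which
also drive the paired AUC comparison test.  Operating points are chosen by
the Youden index, sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "midrank_auc",
    "delong_components",
    "roc_with_delong",
    "delong_compare",
    "combine_predictors",
]


@dataclass
class RocResult:
    """Empirical ROC curve with DeLong inference and Youden cutoff.

    ``negated`` records auto-orientation: when the raw score is lower in
    cases than controls (e.g. mean diffusivity), the score is negated so
    AUC >= 0.5, and the cutoff is reported on the original scale with
    ``direction`` "<=" (test positive at or below the cutoff).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    var: float
    ci_lower: float
    ci_upper: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    negated: bool
    direction: str  # ">=" or "<="


def _split(y, score):
    y = np.asarray(y).astype(int)
    s = np.asarray(score, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values (V10 per case, V01 per control) via midranks.

    ``V10[i]`` is the fraction of controls scored below case i (ties count
    half); symmetrically for ``V01``.  Their means both equal the midrank
    AUC.
    """
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def midrank_auc(y, score) -> float:
    """Empirical AUC = Mann–Whitney U / (n1*n0) with midrank ties."""
    pos, neg = _split(y, score)
    v10, _ = delong_components(pos, neg)
    return float(v10.mean())


def _delong_var(pos, neg):
    v10, v01 = delong_components(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += float(np.var(v10, ddof=1)) / pos.size
    if neg.size > 1:
        var += float(np.var(v01, ddof=1)) / neg.size
    return auc, var


def _roc_curve(pos, neg):
    """Empirical ROC: predict positive when score >= threshold."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    return (np.array(fpr), np.array(tpr),
            np.concatenate([[np.inf], thresholds]))


def roc_with_delong(y, score, auto_orient: bool = True, alpha: float = 0.05) -> RocResult:
    """Empirical ROC with DeLong variance, logit-scale CI and Youden cutoff.

    When ``auto_orient`` and the raw AUC is below 0.5 the score is negated
    (orientation recorded).  The Youden cutoff maximizes sensitivity +
    specificity - 1; ties are broken toward the lower cutoff, i.e. the more
    sensitive operating point.
    """
    pos, neg = _split(y, score)
    negated = False
    if auto_orient and float(delong_components(pos, neg)[0].mean()) < 0.5:
        pos, neg, negated = -pos, -neg, True
    auc, var = _delong_var(pos, neg)
    z = float(norm.ppf(1 - alpha / 2))
    if var <= 0 or auc <= 0 or auc >= 1:
        lo, hi = auc, auc
    else:
        # CI on the log-odds scale keeps the bounds inside (0, 1)
        se_logit = np.sqrt(var) / (auc * (1 - auc))
        lg = np.log(auc / (1 - auc))
        lo = 1 / (1 + np.exp(-(lg - z * se_logit)))
        hi = 1 / (1 + np.exp(-(lg + z * se_logit)))
    fpr, tpr, thr = _roc_curve(pos, neg)
    j = tpr - fpr
    finite = np.isfinite(thr)
    j_f, thr_f = j[finite], thr[finite]
    tpr_f, fpr_f = tpr[finite], fpr[finite]
    best = np.flatnonzero(np.isclose(j_f, j_f.max()))[-1]  # thresholds descend
    cutoff = float(thr_f[best])
    sens, spec = float(tpr_f[best]), float(1 - fpr_f[best])
    if negated:
        cutoff = -cutoff
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, var=var, ci_lower=float(lo), ci_upper=float(hi),
        youden_cutoff=cutoff, sensitivity=sens, specificity=spec,
        negated=negated, direction="<=" if negated else ">=",
    )


def delong_compare(y, score_a, score_b, orient: bool = True):
    """Paired DeLong test for two correlated AUCs on the same cases.

    Returns ``(auc_a, auc_b, diff, z, p)``.  Scores are auto-oriented
    independently (AUC >= 0.5) before comparison, matching how each marker
    would be used diagnostically.  A degenerate variance of the difference
    (identical or rank-identical scores) returns p = 1.
    """
    pos_a, neg_a = _split(y, score_a)
    pos_b, neg_b = _split(y, score_b)
    if orient:
        if float(delong_components(pos_a, neg_a)[0].mean()) < 0.5:
            pos_a, neg_a = -pos_a, -neg_a
        if float(delong_components(pos_b, neg_b)[0].mean()) < 0.5:
            pos_b, neg_b = -pos_b, -neg_b
    v10a, v01a = delong_components(pos_a, neg_a)
    v10b, v01b = delong_components(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    var_a = np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
    var_b = np.var(v10b, ddof=1) / m + np.var(v01b, ddof=1) / n
    cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
           + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
    var_diff = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        return auc_a, auc_b, diff, 0.0, 1.0
    z = diff / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, diff, float(z), p


def combine_predictors(records, predictors, outcome: str = "lnm"):
    """Logistic combination score and its ROC.

    Fits a joint logistic model on the named predictors and uses the fitted
    linear predictor as the ROC score (in-sample, apparent performance).
    Returns ``(score, logit_result, roc_result)``.
    """
    from .stats import multivariate_logit

    fit = multivariate_logit(records, predictors=list(predictors), outcome=outcome)
    score = fit.linear_predictor(records)
    roc = roc_with_delong(records[outcome].to_numpy(int), score)
    return score, fit, roc
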