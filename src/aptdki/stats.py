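"""Group comparisons, contingency tests and logistic regression.

The inferential chain mirrors a standard radiology reader study: a
Kolmogorov–Smirnov normality gate routes each continuous marker to Student's
t-test or the Mann–Whitney U test; categorical covariates get a chi-square
test with Fisher's exact as the small-expected-count fallback; univariate
logistic regressions screen predictors at p < 0.05 for the multivariate
model; odds ratios carry Wald 95 % confidence intervals exp(beta +/- z*SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ContingencyResult",
    "LogitResult",
    "compare_groups",
    "contingency_test",
    "univariate_logit",
    "multivariate_logit",
    "spearman_assoc",
]

ALPHA = 0.05
_Z = float(sps.norm.ppf(0.975))
#: |coefficient| beyond this is treated as (quasi-)complete separation
_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class GroupComparison:
    test: str            # "t" | "mannwhitney"
    statistic: float
    p: float
    normality_p: tuple[float, float]
    note: str = ""


@dataclass(frozen=True)
class ContingencyResult:
    test: str            # "chi2" | "fisher"
    statistic: float
    p: float
    expected_min: float


@dataclass
class LogitResult:
    """Maximum-likelihood logistic fit with Wald inference per predictor.

    ``table`` has one row per predictor (intercept excluded) with columns
    ``coef, se, odds_ratio, ci_lower, ci_upper, p``.
    """

    table: pd.DataFrame
    intercept: float
    loglik: float
    converged: bool
    separation: bool = False
    n_events: int = 0
    epv_warning: bool = False
    predictors: tuple[str, ...] = ()

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Intercept + sum of coef * column over this model's predictors."""
        lp = np.full(len(records), self.intercept)
        for name in self.predictors:
            lp = lp + self.table.loc[name, "coef"] * records[name].to_numpy(float)
        return lp

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(records)))


def _ks_normal_p(x: np.ndarray) -> float:
    """One-sample KS test against a normal with the sample's moments."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # a constant sample is maximally non-normal
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_groups(values, group_labels) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Each group is screened with the Kolmogorov–Smirnov test at alpha = 0.05;
    if both pass, Student's t-test (pooled variance) is used, otherwise the
    Mann–Whitney U test.  A zero-variance group forces the rank test, with a
    note.  The test actually run is always reported.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq.size}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs n >= 3")
    pa, pb = _ks_normal_p(a), _ks_normal_p(b)
    note = ""
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        note = "constant group; forced rank test"
        use_t = False
    else:
        use_t = (pa >= ALPHA) and (pb >= ALPHA)
    if use_t:
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), (pa, pb))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mannwhitney", float(res.statistic),
                           float(min(res.pvalue, 1.0)), (pa, pb), note)


def contingency_test(table) -> ContingencyResult:
    """Chi-square (with continuity correction) or Fisher's exact test.

    Fisher's exact is used whenever any expected cell count falls below 5,
    the conventional validity bound for the chi-square approximation.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    emin = float(expected.min())
    if emin < 5:
        odds, p = sps.fisher_exact(t)
        return ContingencyResult("fisher", float(odds), float(p), emin)
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return ContingencyResult("chi2", float(chi2), float(p), emin)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy(float))
    if rank < design.shape[1]:
        # name the offending columns for the caller
        corr = X.corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1:]
            if corr.loc[a, b] > 0.999
        ]
        raise ValueError(f"singular design matrix; collinear columns: {pairs or 'constant column'}")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    return res, design


def _build_result(res, predictors: list[str], n_events: int) -> LogitResult:
    coefs = res.params
    ses = res.bse
    rows = []
    separation = False
    for name in predictors:
        beta, se = float(coefs[name]), float(ses[name])
        sep = abs(beta) > _SEPARATION_COEF or not np.isfinite(se) or se > 1e3
        separation = separation or sep
        lo, hi = (0.0, np.inf) if sep else (np.exp(beta - _Z * se), np.exp(beta + _Z * se))
        p = float(2 * sps.norm.sf(abs(beta / se))) if se > 0 and np.isfinite(se) else np.nan
        odds = (np.inf if beta > 0 else 0.0) if sep else float(np.exp(beta))
        rows.append({
            "predictor": name, "coef": beta, "se": se,
            "odds_ratio": odds, "ci_lower": float(lo),
            "ci_upper": float(hi), "p": p,
        })
    table = pd.DataFrame(rows).set_index("predictor")
    return LogitResult(
        table=table,
        intercept=float(coefs["const"]),
        loglik=float(res.llf),
        converged=bool(res.converged),
        separation=separation,
        n_events=n_events,
        epv_warning=n_events < 10 * len(predictors),
        predictors=tuple(predictors),
    )


def univariate_logit(records: pd.DataFrame, predictor: str, outcome: str = "lnm") -> LogitResult:
    """Single-predictor logistic regression of the binary outcome.

    For a binary 0/1 predictor the fitted odds ratio equals the 2x2 table's
    cross-product ratio (the logit model is saturated there).  Complete
    separation is flagged and the confidence interval reported as unbounded
    rather than silently huge.
    """
    y = records[outcome].to_numpy(float)
    x = records[[predictor]].astype(float)
    if x[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has no variation")
    res, _ = _fit_logit(y, x)
    return _build_result(res, [predictor], int(y.sum()))


def multivariate_logit(
    records: pd.DataFrame,
    predictors: list[str] | None = None,
    outcome: str = "lnm",
    candidate_predictors: list[str] | None = None,
) -> LogitResult:
    """Joint logistic regression; optional univariate p < 0.05 screening.

    When ``predictors`` is None, each candidate is screened univariately and
    those with Wald p < 0.05 enter the joint model (pipeline mode).  An
    events-per-variable ratio below 10 sets ``epv_warning``.
    """
    if predictors is None:
        if candidate_predictors is None:
            raise ValueError("give predictors or candidate_predictors")
        predictors = [
            c for c in candidate_predictors
            if univariate_logit(records, c, outcome).table.loc[c, "p"] < ALPHA
        ]
        if not predictors:
            raise ValueError("no candidate passed the univariate screen")
    y = records[outcome].to_numpy(float)
    if len(records) < len(predictors) + 1:
        raise ValueError("fewer records than parameters")
    res, _ = _fit_logit(y, records[list(predictors)].astype(float))
    return _build_result(res, list(predictors), int(y.sum()))


def spearman_assoc(records: pd.DataFrame, parameter: str, outcome: str = "lnm"):
    """Spearman rank correlation (midranks) between a marker and the outcome."""
    x = records[parameter].to_numpy(float)
    y = records[outcome].to_numpy(float)
    if x.size < 5:
        raise ValueError("need n >= 5")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input; rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
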