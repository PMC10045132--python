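"""ROC/AUC, DeLong inference, Youden cutoffs, combination score, nomogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, norm

from aptdki.nomogram import nomogram_from_model
from aptdki.roc import combine_predictors, delong_compare, midrank_auc, roc_with_delong
from aptdki.stats import multivariate_logit, univariate_logit


class TestMidrankAuc:
    def test_perfect_separation(self):
        y = np.repeat([0, 1], 5)
        s = np.concatenate([np.arange(5), np.arange(10, 15)])
        roc = roc_with_delong(y, s)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_constant_score_is_chance(self):
        y = np.repeat([0, 1], 6)
        assert midrank_auc(y, np.ones(12)) == pytest.approx(0.5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=8, max_size=40))
    def test_auc_equals_normalized_mannwhitney_u(self, scores):
        """Empirical AUC == U/(n1*n0) with midranks, ties included."""
        y = np.tile([0, 1], len(scores))[: len(scores)]
        if y.sum() in (0, len(y)):
            return
        s = np.asarray(scores, float)
        u = mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        expected = u / (np.sum(y == 1) * np.sum(y == 0))
        assert midrank_auc(y, s) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 60)
        y[:5], y[-5:] = 1, 0
        s = rng.normal(size=60)
        a = midrank_auc(y, s)
        assert midrank_auc(y, np.exp(2 * s) + 3) == pytest.approx(a, abs=1e-12)

    def test_binormal_closed_form_oracle(self):
        """Large-n Gaussian AUC matches Phi(dmu / sqrt(s1^2 + s2^2))."""
        rng = np.random.default_rng(8)
        n = 50_000
        pos = rng.normal(3.7, 1.1, n)
        neg = rng.normal(2.4, 1.0, n)
        y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        auc = midrank_auc(y, np.concatenate([pos, neg]))
        expected = norm.cdf(1.3 / np.sqrt(1.1**2 + 1.0**2))
        assert auc == pytest.approx(expected, abs=0.005)


class TestRocResult:
    def test_curve_monotone(self, rng):
        y = rng.integers(0, 2, 80)
        y[:3], y[-3:] = 1, 0
        roc = roc_with_delong(y, rng.normal(size=80))
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0.5 <= roc.auc <= 1.0

    def test_auto_orientation_of_inverted_marker(self, cohort):
        roc = roc_with_delong(cohort.lnm.to_numpy(), cohort.md.to_numpy())
        assert roc.negated and roc.direction == "<="
        assert roc.auc >= 0.5
        # a case at the cutoff tests positive: md <= cutoff
        sens = np.mean(cohort.md[cohort.lnm == 1] <= roc.youden_cutoff)
        assert sens == pytest.approx(roc.sensitivity, abs=1e-12)

    def test_youden_cutoff_maximizes_j(self, cohort):
        y = cohort.lnm.to_numpy()
        s = cohort.aptw.to_numpy()
        roc = roc_with_delong(y, s)
        j_at_cut = (np.mean(s[y == 1] >= roc.youden_cutoff)
                    + np.mean(s[y == 0] < roc.youden_cutoff) - 1)
        for t in np.unique(s):
            j = np.mean(s[y == 1] >= t) + np.mean(s[y == 0] < t) - 1
            assert j <= j_at_cut + 1e-12

    def test_youden_tie_broken_toward_sensitivity(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([1.0, 2.0, 3.0, 4.0])  # J = 1 at cutoffs 3 and 4
        roc = roc_with_delong(y, s)
        assert roc.youden_cutoff == 3.0

    def test_ci_contains_auc(self, cohort):
        roc = roc_with_delong(cohort.lnm.to_numpy(), cohort.aptw.to_numpy())
        assert roc.ci_lower <= roc.auc <= roc.ci_upper
        assert 0 < roc.ci_lower and roc.ci_upper < 1

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_delong(np.ones(5, int), np.arange(5.0))


class TestDeLong:
    def test_identical_scores_p_one(self, cohort):
        s = cohort.aptw.to_numpy()
        _, _, diff, _, p = delong_compare(cohort.lnm.to_numpy(), s, s)
        assert diff == 0.0 and p == 1.0

    def test_monotone_transform_has_equal_auc(self, cohort):
        s = cohort.aptw.to_numpy()
        auc_a, auc_b, diff, _, p = delong_compare(
            cohort.lnm.to_numpy(), s, np.log(s - s.min() + 1.0))
        assert auc_a == pytest.approx(auc_b, abs=1e-12)
        assert p == 1.0

    def test_variance_matches_bootstrap_oracle(self):
        """DeLong variance vs a stratified, bias-corrected bootstrap (n=12).

        The oracle recomputes each replicate's AUC by brute-force pairwise
        comparison; the per-stratum n/(n-1) factor undoes the plug-in
        shrinkage of the bootstrap variance so both estimate the same
        quantity.
        """
        rng = np.random.default_rng(0)
        pos = rng.normal(1.0, 1.0, 5)
        neg = rng.normal(0.0, 1.0, 7)
        from aptdki.roc import delong_components
        v10, v01 = delong_components(pos, neg)
        dl_var = np.var(v10, ddof=1) / 5 + np.var(v01, ddof=1) / 7

        def brute_auc_many(ps, ns):
            c = (ps[:, :, None] > ns[:, None, :]).astype(float)
            c += 0.5 * (ps[:, :, None] == ns[:, None, :])
            return c.mean(axis=(1, 2))

        B = 50_000
        auc_p = brute_auc_many(pos[rng.integers(0, 5, (B, 5))], neg[None].repeat(B, 0))
        auc_n = brute_auc_many(pos[None].repeat(B, 0), neg[rng.integers(0, 7, (B, 7))])
        boot = auc_p.var(ddof=0) * 5 / 4 + auc_n.var(ddof=0) * 7 / 6
        assert dl_var == pytest.approx(boot, rel=0.05)

    def test_clearly_better_marker_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        y = np.repeat([0, 1], n)
        strong = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        weak = rng.normal(0, 1, 2 * n)
        auc_a, auc_b, diff, z, p = delong_compare(y, strong, weak)
        assert auc_a > auc_b
        assert p < 1e-6


class TestCombination:
    def test_single_predictor_combination_equals_marker_auc(self, cohort):
        _, _, roc = combine_predictors(cohort, ["aptw"])
        direct = roc_with_delong(cohort.lnm.to_numpy(), cohort.aptw.to_numpy())
        assert roc.auc == pytest.approx(direct.auc, abs=1e-12)

    def test_combination_not_below_best_single(self, cohort):
        """In-sample logistic combination cannot undercut its components."""
        _, _, combo = combine_predictors(cohort, ["aptw", "mk", "md"])
        singles = [roc_with_delong(cohort.lnm.to_numpy(),
                                   cohort[c].to_numpy()).auc
                   for c in ("aptw", "mk", "md")]
        assert combo.auc >= max(singles) - 1e-9

    def test_combination_beats_md_alone_in_most_replicates(self):
        from aptdki.cohort import generate_cohort
        wins = 0
        n_rep = 30
        for seed in range(n_rep):
            df = generate_cohort(seed=seed)
            _, _, combo = combine_predictors(df, ["aptw", "mk", "md"])
            md_auc = roc_with_delong(df.lnm.to_numpy(), df.md.to_numpy()).auc
            wins += combo.auc > md_auc
        assert wins > n_rep / 2


class TestNomogram:
    def test_single_predictor_probability_exact(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw"])
        nomo = nomogram_from_model(fit, {"aptw": (cohort.aptw.min(), cohort.aptw.max())})
        pts = nomo.total_points(cohort)
        np.testing.assert_allclose(
            nomo.probability(pts), fit.predict_proba(cohort), atol=1e-9)

    def test_strongest_predictor_spans_0_to_100(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw", "mk", "md"])
        ranges = {p: (cohort[p].min(), cohort[p].max()) for p in fit.predictors}
        nomo = nomogram_from_model(fit, ranges)
        spans = {p: max(nomo.points(p, ranges[p][0]), nomo.points(p, ranges[p][1]))
                 for p in fit.predictors}
        assert max(spans.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(0 <= v <= 100 + 1e-9 for v in spans.values())

    def test_three_predictor_grid_matches_direct_prediction(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw", "mk", "md"])
        ranges = {p: (cohort[p].min(), cohort[p].max()) for p in fit.predictors}
        nomo = nomogram_from_model(fit, ranges)
        grids = np.meshgrid(*[np.linspace(*ranges[p], 6) for p in fit.predictors])
        grid_df = pd.DataFrame({p: g.ravel() for p, g in zip(fit.predictors, grids)})
        direct = fit.predict_proba(grid_df)
        via_points = nomo.probability(nomo.total_points(grid_df))
        assert np.max(np.abs(via_points - direct)) < 1e-6

    def test_points_to_probability_monotone(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw", "mk"])
        ranges = {p: (cohort[p].min(), cohort[p].max()) for p in fit.predictors}
        nomo = nomogram_from_model(fit, ranges)
        probs = nomo.probability(np.linspace(0, 200, 50))
        assert np.all(np.diff(probs) > 0)

    def test_zero_range_predictor_excluded_with_warning(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw", "mk"])
        with pytest.warns(UserWarning, match="zero range"):
            nomo = nomogram_from_model(
                fit, {"aptw": (1.0, 5.0), "mk": (0.9, 0.9)})
        assert nomo.predictors == ("aptw",)

    def test_unconverged_model_rejected(self, cohort):
        fit = multivariate_logit(cohort, predictors=["aptw"])
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            nomogram_from_model(fit, {"aptw": (1.0, 5.0)})
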