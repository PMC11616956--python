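import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gallop import stats as gs


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        # all 20 splits of {1..6}: only the two extreme splits deviate as far
        res = gs.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_samples_p_one(self):
        res = gs.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_symmetry_in_group_order(self):
        x, y = [1.2, 3.4, 2.2, 8.0], [4.4, 0.5, 9.9]
        assert gs.wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            gs.wilcoxon_rank_sum(y, x).p_value
        )

    def test_missing_values_are_dropped(self):
        res = gs.wilcoxon_rank_sum([1, 2, None, float("nan")], [3, 4])
        assert res.n == (2, 2)

    def test_all_missing_is_error(self):
        with pytest.raises(gs.StatsError):
            gs.wilcoxon_rank_sum([None], [1, 2])

    def test_small_samples_use_exact_enumeration(self):
        # the approximation never applies at small n: every split of a
        # pooled n = 8 sample goes through the exact branch
        pooled = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        for n1 in (2, 3, 4):
            for idx in itertools.combinations(range(8), n1):
                x = [pooled[i] for i in idx]
                y = [pooled[i] for i in range(8) if i not in idx]
                assert gs.wilcoxon_rank_sum(x, y).method == "wilcoxon_exact"

    def test_normal_approximation_tracks_exact_in_the_tail(self):
        # exhaustive over all two-group splits of a tied pooled sample: in
        # the decision-relevant tail the continuity-corrected normal
        # approximation stays close to exact enumeration
        pooled = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        for n1 in (2, 3, 4):
            for idx in itertools.combinations(range(8), n1):
                x = [pooled[i] for i in idx]
                y = [pooled[i] for i in range(8) if i not in idx]
                p_exact = gs.wilcoxon_rank_sum(x, y).p_value
                p_norm = gs.wilcoxon_rank_sum(x, y, exact_max_n=0).p_value
                if p_exact <= 0.15:
                    assert abs(p_exact - p_norm) <= 0.05


class TestChiSquare:
    def test_homogeneous_table(self):
        res = gs.chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2))
            plain = gs.chi_square(t).statistic
            yates = gs.chi_square(t, continuity=True).statistic
            assert yates <= plain + 1e-12

    def test_zero_marginal_is_error(self):
        with pytest.raises(gs.StatsError):
            gs.chi_square([[0, 0], [5, 3]])

    def test_df_for_rxc(self):
        res = gs.chi_square([[5, 6, 7], [8, 9, 10]])
        assert res.df == 2


class TestFisherExact:
    def test_matches_hypergeometric_enumeration(self):
        # independent oracle: sum hypergeometric pmf over the support
        table = [[1, 9], [9, 1]]
        res = gs.fisher_exact(table)
        n1, n2 = 10, 10
        k = 10  # first-column total
        obs = sps.hypergeom.pmf(1, n1 + n2, n1, k)
        p_brute = sum(
            sps.hypergeom.pmf(x, n1 + n2, n1, k)
            for x in range(max(0, k - n2), min(n1, k) + 1)
            if sps.hypergeom.pmf(x, n1 + n2, n1, k) <= obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p_brute)

    def test_symmetric_table_p_one(self):
        assert gs.fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_transpose_invariance(self):
        t = [[3, 8], [12, 5]]
        tt = [[3, 12], [8, 5]]
        assert gs.fisher_exact(t).p_value == pytest.approx(gs.fisher_exact(tt).p_value)

    def test_zero_marginal_convention(self):
        res = gs.fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0 and res.note is not None


class TestFisherPower:
    def test_size_under_the_null(self):
        power = gs.fisher_power_two_proportions(15, 15, 0.5, 0.5, alpha=0.05)
        assert power <= 0.05

    def test_monotone_in_effect_size(self):
        powers = [
            gs.fisher_power_two_proportions(20, 20, 0.5, 0.5 + d, alpha=0.05)
            for d in (0.1, 0.25, 0.4)
        ]
        assert powers[0] < powers[1] < powers[2]

    def test_invalid_proportion_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.fisher_power_two_proportions(10, 10, 0.0, 0.5)


class TestLogisticFit:
    def test_two_by_two_closed_form_or(self):
        # exposure table [[10,5],[4,11]]: OR = (10*11)/(5*4) = 5.5 exactly
        x = [1] * 10 + [0] * 5 + [1] * 4 + [0] * 11
        y = [1] * 15 + [0] * 15
        fit = gs.logistic_fit(pd.DataFrame({"x": x}), y)
        i = fit.names.index("x")
        assert fit.odds_ratios[i] == pytest.approx(5.5, rel=1e-6)

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(gs.StatsError, match="variance"):
            gs.logistic_fit(pd.DataFrame({"x": [1.0] * 10}), [0, 1] * 5)

    def test_perfect_separation_names_covariate(self):
        x = list(range(10))
        y = [0] * 5 + [1] * 5
        with pytest.raises(gs.StatsError, match="x"):
            gs.logistic_fit(pd.DataFrame({"x": x}), y)

    def test_matches_likelihood_grid_search(self):
        # brute-force likelihood maximisation oracle on a 20-row fixture
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        if y.min() == y.max():  # fixture guard
            y[0] = 1 - y[0]
        fit = gs.logistic_fit(pd.DataFrame({"x": x}), y)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        b0g, b1g = 0.0, 0.0
        for width in (4.0, 0.5, 0.05, 0.005, 0.0005):
            grid0 = np.linspace(b0g - width, b0g + width, 41)
            grid1 = np.linspace(b1g - width, b1g + width, 41)
            vals = [(nll(a, b), a, b) for a in grid0 for b in grid1]
            _, b0g, b1g = min(vals)
        assert fit.estimates[fit.names.index("intercept")] == pytest.approx(b0g, abs=1e-4)
        assert fit.estimates[fit.names.index("x")] == pytest.approx(b1g, abs=1e-4)

    def test_aic_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(int)
        fit = gs.logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)


def _two_strata_fixture():
    # two 1:3 strata with a scalar covariate; the case is not the extreme
    # member of every stratum, so the conditional MLE is finite
    x = np.array([1.0, 2.0, 0.5, 0.0, 3.0, 2.5, 1.0, 2.0])
    y = np.array([1, 0, 0, 0, 1, 0, 0, 0])
    g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return x, y, g


def _cond_loglik(beta, x, y, g):
    ll = 0.0
    for s in np.unique(g):
        m = g == s
        eta = beta * x[m]
        ll += eta[y[m] == 1][0] - math.log(np.sum(np.exp(eta)))
    return ll


class TestConditionalLogistic:
    def test_matches_1d_brute_force_maximisation(self):
        x, y, g = _two_strata_fixture()
        fit = gs.conditional_logistic_fit(pd.DataFrame({"x": x}), y, g)
        grid = np.linspace(-5, 5, 200001)
        lls = [_cond_loglik(b, x, y, g) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.estimates[0] == pytest.approx(b_star, abs=1e-4)

    def test_null_loglik_is_minus_sum_log_stratum_sizes(self):
        x, y, g = _two_strata_fixture()
        fit = gs.conditional_logistic_fit(pd.DataFrame({"x": x}), y, g)
        assert fit.loglik_null == pytest.approx(-2 * math.log(4))

    def test_stratum_constant_covariate_unidentifiable(self):
        y = np.array([1, 0, 0, 1, 0, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 5.0])
        with pytest.raises(gs.StatsError):
            gs.conditional_logistic_fit(pd.DataFrame({"x": x}), y, g)

    def test_invariant_to_stratum_constant_shift(self):
        x, y, g = _two_strata_fixture()
        shifted = x + np.where(g == 0, 10.0, -3.0)
        f1 = gs.conditional_logistic_fit(pd.DataFrame({"x": x}), y, g)
        f2 = gs.conditional_logistic_fit(pd.DataFrame({"x": shifted}), y, g)
        assert f1.estimates[0] == pytest.approx(f2.estimates[0], abs=1e-5)

    def test_stratum_without_single_case_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.conditional_logistic_fit(
                pd.DataFrame({"x": [1.0, 2.0]}), [0, 0], [0, 0]
            )


class TestBoxTidwell:
    @staticmethod
    def _simulate(transform, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 10, n)
        eta = -2.0 + 0.5 * transform(x)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return x, y

    def test_linear_logit_passes(self):
        x, y = self._simulate(lambda x: x)
        assert gs.box_tidwell(x, y).p_value > 0.05

    def test_quadratic_logit_fails(self):
        x, y = self._simulate(lambda x: 0.2 * x**2)
        assert gs.box_tidwell(x, y).p_value < 0.05

    def test_scaling_preserves_conclusion(self):
        x, y = self._simulate(lambda x: 0.2 * x**2)
        assert gs.box_tidwell(x * 3.7, y).p_value < 0.05
        xl, yl = self._simulate(lambda x: x)
        assert gs.box_tidwell(xl * 3.7, yl).p_value > 0.05

    def test_negative_values_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.box_tidwell([-1.0, 2.0, 3.0, 1.0], [0, 1, 0, 1])


class TestQuartileCategorize:
    def test_one_to_eight(self):
        codes, cuts, labels = gs.quartile_categorize(list(range(1, 9)))
        assert codes.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]
        assert len(labels) == 4

    def test_value_on_cutpoint_goes_to_lower_band(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        codes, cuts, _ = gs.quartile_categorize(x)
        at_cut = np.searchsorted(cuts, cuts[1], side="left")
        assert at_cut == 1  # the cutpoint itself belongs below

    def test_balanced_band_counts_for_distinct_values(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.permutation(rng.uniform(0, 100, rng.integers(8, 40)))
            codes, _, _ = gs.quartile_categorize(x)
            counts = np.bincount(codes, minlength=4)
            assert counts.max() - counts.min() <= 2

    def test_too_few_distinct_values(self):
        with pytest.raises(gs.StatsError):
            gs.quartile_categorize([1.0, 1.0, 2.0, 3.0])


class TestStepwiseAIC:
    @staticmethod
    def _planted(n=1000, seed=8):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 1.2 * x1)))).astype(int)
        return pd.DataFrame({"x1": x1, "x2": x2}), y

    def test_signal_kept_noise_dropped(self):
        X, y = self._planted()
        res = gs.stepwise_aic(X, y, direction="stepwise")
        assert res.selected == ("x1",)

    def test_backward_keeps_signal(self):
        X, y = self._planted()
        res = gs.stepwise_aic(X[["x1"]], y, direction="backward")
        assert res.selected == ("x1",)

    def test_final_aic_never_exceeds_intercept_only(self):
        X, y = self._planted(n=300, seed=5)
        res = gs.stepwise_aic(X, y)
        null_aic = gs.stepwise_aic(X.iloc[:, :0].assign(z=0.0), y).fit.aic \
            if False else None
        intercept = gs._intercept_only_fit(np.asarray(y))
        assert res.fit.aic <= intercept.aic + 1e-9

    def test_empty_screen_returns_flagged_intercept_model(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"noise": rng.normal(size=200)})
        y = (rng.random(200) < 0.5).astype(int)
        res = gs.stepwise_aic(X, y, screen_p=1e-6)
        assert res.flagged_empty and res.selected == ()


class TestHosmerLemeshow:
    def _fixture_fit(self):
        # 20 rows, distinct fitted probabilities, 10 groups of 2
        p = np.linspace(0.05, 0.95, 20)
        y = np.array([0, 0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
        return gs.LogisticModelFit(
            method="logistic", names=("intercept",), estimates=(0.0,),
            std_errors=(1.0,), p_values=(1.0,), loglik=0.0, loglik_null=0.0,
            aic=2.0, n=20, outcome=tuple(int(v) for v in y),
            fitted=tuple(float(v) for v in p),
        )

    def test_matches_hand_computed_decile_table(self):
        fit = self._fixture_fit()
        res = gs.hosmer_lemeshow(fit, groups=10)
        p = np.asarray(fit.fitted)
        y = np.asarray(fit.outcome)
        stat = 0.0
        for g in range(10):  # groups of two, in fitted order
            sl = slice(2 * g, 2 * g + 2)
            e1 = p[sl].sum()
            o1 = y[sl].sum()
            stat += (o1 - e1) ** 2 / e1 + ((2 - o1) - (2 - e1)) ** 2 / (2 - e1)
        assert res.statistic == pytest.approx(stat)
        assert res.df == 8

    def test_too_few_groups_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.hosmer_lemeshow(self._fixture_fit(), groups=2)

    def test_too_few_distinct_fitted_values(self):
        fit = self._fixture_fit()
        flat = gs.LogisticModelFit(
            **{**fit.__dict__, "fitted": tuple([0.5] * 20)}
        )
        with pytest.raises(gs.StatsError, match="fewer groups"):
            gs.hosmer_lemeshow(flat, groups=10)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        # well-specified logistic model: HL should reject ~5% of the time
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=250)
            y = (rng.random(250) < 1 / (1 + np.exp(-(0.3 + 0.9 * x)))).astype(int)
            if y.min() == y.max():
                continue
            fit = gs.logistic_fit(pd.DataFrame({"x": x}), y)
            if gs.hosmer_lemeshow(fit, groups=10).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.15


class TestRocAuc:
    def _fit(self, y, scores):
        return gs.LogisticModelFit(
            method="logistic", names=("intercept",), estimates=(0.0,),
            std_errors=(1.0,), p_values=(1.0,), loglik=0.0, loglik_null=0.0,
            aic=2.0, n=len(y), outcome=tuple(y), fitted=tuple(scores),
        )

    def test_perfect_separation_auc_one(self):
        assert gs.roc_auc(self._fit([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_scores_auc_half(self):
        assert gs.roc_auc(self._fit([0, 1, 0, 1], [0.5] * 4)) == 0.5

    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(6)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0])
        s = rng.random(12)
        s[3] = s[5]  # inject a tie across classes
        auc = gs.roc_auc(self._fit(y.tolist(), s.tolist()))
        num = 0.0
        pairs = 0
        for i in np.where(y == 1)[0]:
            for j in np.where(y == 0)[0]:
                pairs += 1
                num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert auc == pytest.approx(num / pairs)

    def test_monotone_transform_invariance(self):
        y = [0, 1, 0, 1, 1, 0, 1]
        s = [0.1, 0.4, 0.35, 0.8, 0.6, 0.2, 0.55]
        a1 = gs.roc_auc(self._fit(y, s))
        a2 = gs.roc_auc(self._fit(y, [math.exp(3 * v) for v in s]))
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(gs.StatsError):
            gs.roc_auc(self._fit([1, 1, 1], [0.2, 0.3, 0.4]))
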