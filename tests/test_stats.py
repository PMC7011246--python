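import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radiotex.errors import DegenerateInputError, UndefinedCorrelationError
from radiotex.stats import (
    cohens_d_summary,
    feature_survival_screen,
    group_compare,
    km_estimate,
    pearson_assoc,
)


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        res = pearson_assoc(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_t_statistic_closed_form(self):
        # with r = 0.78 and n = 16: t = 0.78 * sqrt(14 / (1 - 0.6084)) ~ 4.666
        rng = np.random.default_rng(0)
        # construct data with exactly the target r via Gram-Schmidt
        x = rng.normal(size=16)
        e = rng.normal(size=16)
        x = (x - x.mean()) / x.std()
        e = e - e.mean() - x * (e @ x) / (x @ x) * 1.0
        e /= np.sqrt((e**2).mean())
        r_target = 0.78
        y = r_target * x + np.sqrt(1 - r_target**2) * e
        res = pearson_assoc(x, y)
        assert res.r == pytest.approx(0.78, abs=1e-12)
        assert res.t_stat == pytest.approx(0.78 * np.sqrt(14 / (1 - 0.78**2)), abs=1e-9)
        assert res.t_stat == pytest.approx(4.666, abs=0.01)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=(2, 30))
            res = pearson_assoc(x, y)
            r_oracle = float(((x - x.mean()) * (y - y.mean())).sum()
                             / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
            assert res.r == pytest.approx(r_oracle, abs=1e-12)
            assert res.p == pytest.approx(sps.pearsonr(x, y).pvalue, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        ps = [pearson_assoc(rng.normal(size=20), rng.normal(size=20)).p
              for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.001

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_assoc(np.ones(10), np.arange(10.0))


class TestGroupCompare:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_compare(a, a)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.cohens_d == 0.0

    @pytest.mark.parametrize(
        "m1, s1, m2, s2, expected",
        [
            (19.98, 13.2, -12.10, 5.63, 3.162),  # gradient-histogram entropy, fibrosis
            (19.77, 9.84, -10.42, 4.33, 3.971),  # gradient-histogram entropy, CK19
            (0.06, 0.02, 0.18, 0.08, 2.058),  # diagonal-band variance, CK19
            (0.52, 0.13, 0.30, 0.05, 2.233),  # vertical-band long-run emphasis, CK19
        ],
    )
    def test_equal_weight_pooled_d_from_summary_statistics(self, m1, s1, m2, s2, expected):
        assert cohens_d_summary(m1, s1, m2, s2) == pytest.approx(expected, rel=1e-3)

    def test_full_data_path_agrees_with_summary_path_at_equal_n(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 12)
        res = group_compare(a, b)
        assert res.cohens_d == pytest.approx(
            cohens_d_summary(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1)), abs=1e-12
        )

    def test_d_is_reported_unsigned(self):
        rng = np.random.default_rng(4)
        lo, hi = rng.normal(0, 1, 10), rng.normal(3, 1, 10)
        assert group_compare(lo, hi).cohens_d == pytest.approx(group_compare(hi, lo).cohens_d)
        assert group_compare(lo, hi).cohens_d > 0

    def test_matches_scipy_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 11)
        res = group_compare(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        est = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        curve = est.curves["all"]
        probs = dict(zip(curve["time"], curve["survival_prob"]))
        assert probs[1.0] == pytest.approx(2 / 3)
        assert probs[2.0] == pytest.approx(1 / 3)
        assert probs[3.0] == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        est = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        curve = est.curves["all"]
        probs = dict(zip(curve["time"], curve["survival_prob"]))
        assert probs[1.0] == pytest.approx(2 / 3)
        assert probs[3.0] == pytest.approx(0.0)  # risk set at t=3 is 1

    def test_identical_groups_null_logrank(self):
        times = [3.0, 5.0, 7.0, 9.0] * 2
        groups = ["a"] * 4 + ["b"] * 4
        est = km_estimate(times, [True] * 8, groups)
        assert est.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert est.logrank_p == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(1, 100, size=25)
        est = km_estimate(t, np.ones(25, bool))
        curve = est.curves["all"]
        for time, prob in zip(curve["time"], curve["survival_prob"]):
            if time == 0:
                continue
            assert prob == pytest.approx((t > time).mean(), abs=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(DegenerateInputError):
            km_estimate([0.0, 1.0], [True, True])


class TestSurvivalScreen:
    def test_linked_feature_ranks_first(self):
        rng = np.random.default_rng(7)
        n = 40
        latent = rng.normal(size=n)
        tab = pd.DataFrame(
            {
                "linked": latent + 0.2 * rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        surv = 30 + 10 * latent + rng.normal(size=n)
        screen = feature_survival_screen(tab, surv)
        assert screen.iloc[0]["feature"] == "linked"
        assert bool(screen.iloc[0]["significant"])

    def test_duplicated_subject_gives_undefined_correlation(self):
        tab = pd.DataFrame({"f": np.ones(6)})
        with pytest.raises(UndefinedCorrelationError):
            feature_survival_screen(tab, np.arange(1.0, 7.0))

    def test_bh_adjustment_is_off_by_default_and_available(self):
        rng = np.random.default_rng(8)
        tab = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        surv = rng.uniform(10, 100, size=20)
        plain = feature_survival_screen(tab, surv)
        adjusted = feature_survival_screen(tab, surv, bh_adjust=True)
        assert "q" not in plain.columns
        assert (adjusted["q"] >= adjusted["p"] - 1e-12).all()
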