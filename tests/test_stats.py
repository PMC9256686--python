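"""Statistical kernels against independent oracles and their exact examples."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from corticospinal.stats import (
    DegenerateDataError,
    holm_bonferroni,
    ols_fit,
    paired_t,
    pearson_correlation,
    rm_anova_3way,
    simple_regression,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(diffs):
    """Enumerate all 2^n sign assignments for the exact two-tailed p."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_three_point_example(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.value == 6.0
        assert res.p == pytest.approx(0.25)

    def test_symmetric_pair_has_p_one(self):
        assert wilcoxon_signed_rank([0.7, -0.7]).p == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = np.round(rng.normal(0.4, 1.0, n), 1)  # rounding induces ties
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 12)
            ours = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="exact")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.2, 1.0, 60)
        ours = wilcoxon_signed_rank(d, method="approx")
        ref = scipy.stats.wilcoxon(d, method="approx", correction=True)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestHolm:
    def test_stepdown_example(self):
        out = holm_bonferroni([0.01, 0.03, 0.04])
        assert out == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 15)
        ours = holm_bonferroni(p)
        ref = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_dominates_raw_and_capped(self, p):
        out = holm_bonferroni(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-15)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            holm_bonferroni([])


class TestOLS:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        fit = ols_fit(x[:, None], 3.0 + 2.0 * x)
        assert fit.metrics.r2 == pytest.approx(1.0)
        assert fit.metrics.adjusted_r2 == pytest.approx(1.0)
        assert fit.params == pytest.approx([3.0, 2.0])

    def test_adjustment_formula(self):
        # adj R2 = 1 - (1 - R2)(n-1)/(n-k-1); at R2=0.477, n=13, k=1 -> 0.4295
        rng = np.random.default_rng(3)
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        fit = ols_fit(x[:, None], y)
        m = fit.metrics
        assert m.adjusted_r2 == pytest.approx(1 - (1 - m.r2) * 12 / 11)
        assert 1 - (1 - 0.477) * 12 / 11 == pytest.approx(0.4295, abs=5e-5)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.normal(size=(20, 3))
            y = X @ rng.normal(size=3) + rng.normal(size=20)
            fit = ols_fit(X, y)
            ref = sm.OLS(y, sm.add_constant(X)).fit()
            assert fit.params == pytest.approx(ref.params, abs=1e-10)
            assert fit.metrics.r2 == pytest.approx(ref.rsquared, abs=1e-12)
            assert fit.metrics.adjusted_r2 == pytest.approx(ref.rsquared_adj, abs=1e-12)
            assert fit.f.value == pytest.approx(ref.fvalue, rel=1e-10)
            assert fit.f.p == pytest.approx(ref.f_pvalue, abs=1e-12)

    def test_information_criteria_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = ols_fit(X, y).metrics
        n, k = m.n, m.k
        assert m.aic == pytest.approx(n * np.log(m.rss / n) + 2 * (k + 2))
        assert m.bic == pytest.approx(n * np.log(m.rss / n) + np.log(n) * (k + 2))

    def test_rank_deficiency_errors(self):
        x = np.ones((10, 1))
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(np.hstack([x, x]), np.arange(10.0))


class TestSimpleRegression:
    def test_exact_line(self):
        slope, intercept, r, r2 = simple_regression([0, 1, 2], [0, 2, 4])
        assert (slope, intercept, r2) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_response(self):
        slope, _, r, r2 = simple_regression([0, 1, 2], [5, 5, 5])
        assert (slope, r, r2) == (0.0, 0.0, 0.0)

    def test_constant_explanatory_errors(self):
        with pytest.raises(DegenerateDataError):
            simple_regression([1, 1, 1], [0, 1, 2])

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(size=11)
            y = rng.normal(size=11)
            slope, _, r, r2 = simple_regression(x, y)
            cov = np.cov(x, y, ddof=1)
            assert slope == pytest.approx(cov[0, 1] / cov[0, 0], abs=1e-10)
            assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)
            assert r2 == pytest.approx(r * r, abs=1e-12)


class TestRmAnova:
    @staticmethod
    def _random_table(rng, n=8):
        rows = []
        for s in range(n):
            for a in ("RHM", "LHM"):
                for b in ("C5", "C7Th1"):
                    for c in ("contra", "ipsi"):
                        rows.append(
                            {
                                "participant_id": f"s{s}",
                                "hand": a,
                                "segment": b,
                                "side": c,
                                "beta": rng.normal(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        table = self._random_table(rng)
        ours = {r.name: r for r in rm_anova_3way(table)}
        ref = AnovaRM(
            table,
            depvar="beta",
            subject="participant_id",
            within=["hand", "segment", "side"],
        ).fit()
        mapping = {
            "hand": "hand",
            "segment": "segment",
            "side": "side",
            "hand:segment": "hand:segment",
            "hand:side": "hand:side",
            "segment:side": "segment:side",
            "hand:segment:side": "hand:segment:side",
        }
        for ours_name, ref_name in mapping.items():
            row = ref.anova_table.loc[ref_name]
            assert ours[ours_name].value == pytest.approx(row["F Value"], rel=1e-8)
            assert ours[ours_name].p == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(8)
        table = self._random_table(rng, n=10)
        results = {r.name: r for r in rm_anova_3way(table)}
        # SEGMENT main effect == squared paired t on per-subject segment means
        means = (
            table.groupby(["participant_id", "segment"])["beta"].mean().unstack()
        )
        t = paired_t(means["C7Th1"].to_numpy(), means["C5"].to_numpy())
        assert results["segment"].value == pytest.approx(t.value**2, rel=1e-10)
        assert results["segment"].p == pytest.approx(t.p, abs=1e-12)

    def test_df_convention(self):
        rng = np.random.default_rng(9)
        table = self._random_table(rng, n=13)
        for r in rm_anova_3way(table):
            assert r.df == (1.0, 12.0)

    def test_constant_table_signals(self):
        table = self._random_table(np.random.default_rng(10))
        table["beta"] = 1.0
        with pytest.raises(DegenerateDataError):
            rm_anova_3way(table)

    def test_missing_cell_errors(self):
        table = self._random_table(np.random.default_rng(11))
        with pytest.raises(ValueError):
            rm_anova_3way(table.iloc[1:])


class TestPairedAndPearson:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.value, res.p) == (0.0, 1.0)

    def test_t_definition(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 13))
        res = paired_t(x, y)
        d = x - y
        assert res.value == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(13)), rel=1e-12
        )
        assert res.df == 12.0

    def test_pearson_constant_errors(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlation([1, 1, 1], [0, 1, 2])
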