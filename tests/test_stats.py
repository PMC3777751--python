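"""Statistical battery: t-tests, chi-square, group model, partial
correlation, hierarchical stepwise regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from aslprodrome.stats import (
    chi2_frequencies,
    group_model,
    partial_correlation,
    stepwise_hierarchical,
    ttest_from_summary,
)


def sample_with_moments(mean, sd, n, rng):
    """Sample whose sample mean/SD match the summaries exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestTtestFromSummary:
    @pytest.mark.parametrize(
        "g1, g2, expected_t, expected_df",
        [
            ((73.0, 7.0, 44), (68.7, 7.2, 31), 2.6, 73),  # CN vs EMCI age
            ((68.7, 7.2, 31), (75.6, 8.8, 15), -2.8, 44),  # EMCI vs AD age
            ((68.7, 7.2, 31), (72.3, 7.4, 30), -1.9, 59),  # EMCI vs LMCI age
        ],
    )
    def test_cohort_age_comparisons(self, g1, g2, expected_t, expected_df):
        t, df, p = ttest_from_summary(*g1, *g2)
        assert round(t, 1) == expected_t
        assert df == expected_df

    def test_identical_summaries_give_null(self):
        t, df, p = ttest_from_summary(10, 2, 20, 10, 2, 25)
        assert t == 0.0 and p == 1.0

    def test_matches_raw_data_t(self):
        rng = np.random.default_rng(0)
        a = sample_with_moments(50.0, 8.0, 40, rng)
        b = sample_with_moments(45.0, 9.0, 25, rng)
        t_sum, df, p_sum = ttest_from_summary(50, 8, 40, 45, 9, 25)
        t_raw, p_raw = sps.ttest_ind(a, b, equal_var=True)
        assert t_sum == pytest.approx(t_raw, rel=1e-10)
        assert p_sum == pytest.approx(p_raw, rel=1e-10)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.5, 20), s2=st.floats(0.5, 20),
        n1=st.integers(2, 200), n2=st.integers(2, 200),
    )
    def test_antisymmetry(self, m1, m2, s1, s2, n1, n2):
        t_ab, df_ab, p_ab = ttest_from_summary(m1, s1, n1, m2, s2, n2)
        t_ba, df_ba, p_ba = ttest_from_summary(m2, s2, n2, m1, s1, n1)
        assert t_ab == pytest.approx(-t_ba, abs=1e-12)
        assert df_ab == df_ba
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1, 0, 10, 2, 1, 10)


class TestChi2:
    def test_sex_imbalance_detected(self):
        # female:male CN 26:18 vs AD 4:11
        chi2, df, p = chi2_frequencies(np.array([[26, 18], [4, 11]]))
        assert df == 1
        assert p < 0.05

    def test_proportional_table_gives_zero(self):
        chi2, df, p = chi2_frequencies(np.array([[20, 30], [10, 15]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_loop(self):
        table = np.array([[26.0, 18.0], [4.0, 11.0]])
        chi2, _, _ = chi2_frequencies(table)
        total = table.sum()
        acc = 0.0
        for i in range(2):
            for j in range(2):
                expected = table[i].sum() * table[:, j].sum() / total
                acc += (table[i, j] - expected) ** 2 / expected
        assert chi2 == pytest.approx(acc, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_frequencies(np.array([[0, 0], [5, 7]]))


def two_group_frame(rng, n1=20, n2=15, delta=1.0):
    y = np.concatenate([rng.normal(0, 1, n1), rng.normal(delta, 1, n2)])
    return pd.DataFrame({
        "y": y,
        "group": ["CN"] * n1 + ["AD"] * n2,
    })


class TestGroupModel:
    def test_single_dummy_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        df = two_group_frame(rng)
        res = group_model(df, "y", covariates=())
        a = df.loc[df.group == "CN", "y"]
        b = df.loc[df.group == "AD", "y"]
        t_ref, _ = sps.ttest_ind(b, a, equal_var=True)
        c = res.contrasts[0]
        assert c.t == pytest.approx(t_ref, rel=1e-10)
        assert res.group_F == pytest.approx(t_ref**2, rel=1e-8)
        assert res.overall_F == pytest.approx(t_ref**2, rel=1e-8)

    def test_matches_hand_rolled_ols_with_covariate(self):
        rng = np.random.default_rng(2)
        n = 60
        groups = rng.choice(["CN", "EMCI", "LMCI", "AD"], size=n, p=[0.4, 0.25, 0.2, 0.15])
        age = rng.normal(72, 7, n)
        y = rng.normal(45, 8, n) - 3 * (groups == "AD") + 0.1 * age
        df = pd.DataFrame({"y": y, "group": groups, "age": age})
        res = group_model(df, "y")
        # independent oracle: explicit lstsq on the same design
        others = [g for g in pd.unique(groups) if g != "CN"]
        X = np.column_stack(
            [np.ones(n)] + [(groups == g).astype(float) for g in others] + [age]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df_resid = n - X.shape[1]
        sigma2 = resid @ resid / df_resid
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
        for j, g in enumerate(others):
            c = next(c for c in res.contrasts if c.group == g)
            assert c.t == pytest.approx(beta[1 + j] / se[1 + j], rel=1e-9)

    def test_constant_outcome_gives_zero_contrasts(self):
        df = pd.DataFrame({
            "y": np.ones(40),
            "group": ["CN"] * 20 + ["AD"] * 20,
            "age": np.random.default_rng(3).normal(70, 5, 40),
        })
        res = group_model(df, "y")
        assert res.contrasts[0].t == 0.0
        assert res.contrasts[0].cohens_d == 0.0

    def test_missing_reference_group_rejected(self):
        df = two_group_frame(np.random.default_rng(4))
        df["group"] = "AD"
        with pytest.raises(ValueError, match="reference"):
            group_model(df, "y", covariates=())

    def test_built_in_deficit_recovered(self):
        # one pooled-SD deficit in the AD group: contrast negative, |d| near 1
        rng = np.random.default_rng(5)
        n_per = {"CN": 44, "EMCI": 31, "LMCI": 30, "AD": 15}
        ds = []
        for rep in range(10):
            rows = []
            for g, n in n_per.items():
                mu = 45.0 - (8.0 if g == "AD" else 0.0)
                for v in rng.normal(mu, 8.0, n):
                    rows.append({"y": v, "group": g, "age": rng.normal(72, 7)})
            res = group_model(pd.DataFrame(rows), "y")
            ad = next(c for c in res.contrasts if c.group == "AD")
            assert ad.t < 0
            ds.append(ad.cohens_d)
        assert np.mean(ds) == pytest.approx(-1.0, abs=0.3)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(6)
        df = two_group_frame(rng, n1=25, n2=20)
        df.loc[3, "y"] = np.nan
        res = group_model(df, "y", covariates=())
        assert res.n_used == 44


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_perfect_residual_association(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(40, 2))
        x = rng.normal(size=40)
        y = x + z @ np.array([2.0, -1.0])
        r, p = partial_correlation(x, y, z)
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_inverse_correlation_matrix_identity(self):
        rng = np.random.default_rng(9)
        n = 80
        z = rng.normal(size=(n, 2))
        x = z @ np.array([0.5, 0.2]) + rng.normal(size=n)
        y = z @ np.array([-0.3, 0.4]) + 0.4 * x + rng.normal(size=n)
        r, _ = partial_correlation(x, y, z)
        corr = np.corrcoef(np.column_stack([x, y, z]), rowvar=False)
        omega = np.linalg.inv(corr)
        r_oracle = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
        assert r == pytest.approx(r_oracle, rel=1e-10)

    def test_symmetry_in_x_and_y(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(30, 1))
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r_xy, p_xy = partial_correlation(x, y, z)
        r_yx, p_yx = partial_correlation(y, x, z)
        assert r_xy == pytest.approx(r_yx, rel=1e-12)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(4), np.ones(4), np.ones((4, 2)))


def stepwise_oracle(df, outcome, forced, candidates, p_enter):
    """Exhaustive evaluation of the 4 possible models under the entry rule,
    independent of the implementation's loop."""
    data = df[list(dict.fromkeys([outcome, *forced, *candidates]))].dropna()
    n = len(data)

    def z(col):
        v = data[col].to_numpy(float)
        return (v - v.mean()) / v.std(ddof=1)

    def coef_p(cols, target_idx):
        X = np.column_stack([np.ones(n)] + [z(c) for c in cols])
        y = z(outcome)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfres = n - X.shape[1]
        sigma2 = resid @ resid / dfres
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
        t = beta[1 + target_idx] / se[1 + target_idx]
        return 2 * sps.t.sf(abs(t), dfres)

    entered = []
    remaining = list(candidates)
    while remaining:
        pvals = {
            c: coef_p(list(forced) + entered + [c], len(forced) + len(entered))
            for c in remaining
        }
        best = min(pvals, key=pvals.get)
        if pvals[best] >= p_enter:
            break
        entered.append(best)
        remaining.remove(best)
    return entered


class TestStepwise:
    def _frame(self, rng, b_cbf=-0.4, b_hippo=-0.5, noise=1.0, n=120):
        age = rng.normal(72, 7, n)
        edu = rng.normal(16, 3, n)
        cbf = rng.normal(45, 8, n)
        hippo = rng.normal(0.0023, 0.0003, n)
        y = (
            0.02 * age - 0.05 * edu
            + b_cbf * (cbf - 45) / 8 + b_hippo * (hippo - 0.0023) / 0.0003
            + rng.normal(0, noise, n)
        )
        return pd.DataFrame({
            "cdr_sb": y, "age": age, "education": edu,
            "meta_roi_cbf": cbf, "hippo_norm": hippo,
        })

    def test_strong_effects_both_entered_with_signs(self):
        rng = np.random.default_rng(11)
        df = self._frame(rng)
        res = stepwise_hierarchical(df, "cdr_sb")
        names = [e[0] for e in res.entered]
        assert set(names) == {"meta_roi_cbf", "hippo_norm"}
        betas = {e[0]: e[1] for e in res.entered}
        assert betas["meta_roi_cbf"] < 0 and betas["hippo_norm"] < 0
        assert all(e[2] < 0.05 for e in res.entered)

    def test_pure_noise_candidate_rarely_entered(self):
        entered_count = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            df = self._frame(rng, b_cbf=0.0, b_hippo=-0.6)
            res = stepwise_hierarchical(df, "cdr_sb")
            if "meta_roi_cbf" in [e[0] for e in res.entered]:
                entered_count += 1
        # null candidate enters at ~ the 5% entry level
        assert entered_count <= 6

    def test_threshold_disabled_equals_full_model(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        df = self._frame(rng, b_cbf=0.0, b_hippo=0.0, noise=2.0)
        res = stepwise_hierarchical(df, "cdr_sb", p_enter=1.0)
        assert {e[0] for e in res.entered} == {"meta_roi_cbf", "hippo_norm"}

        def z(col):
            v = df[col].to_numpy(float)
            return (v - v.mean()) / v.std(ddof=1)

        X = np.column_stack([np.ones(len(df))] + [
            z(c) for c in ("age", "education", *[e[0] for e in res.entered])
        ])
        full = sm.OLS(z("cdr_sb"), X).fit()
        betas = {e[0]: e[1] for e in res.entered}
        for i, name in enumerate([e[0] for e in res.entered]):
            assert betas[name] == pytest.approx(full.params[3 + i], rel=1e-9)
        assert res.final_F == pytest.approx(full.fvalue, rel=1e-9)

    def test_agrees_with_exhaustive_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            b1 = rng.uniform(-0.4, 0.4)
            b2 = rng.uniform(-0.4, 0.4)
            df = self._frame(rng, b_cbf=b1, b_hippo=b2, noise=1.5, n=60)
            res = stepwise_hierarchical(df, "cdr_sb")
            oracle = stepwise_oracle(
                df, "cdr_sb", ("age", "education"),
                ("meta_roi_cbf", "hippo_norm"), 0.05,
            )
            assert [e[0] for e in res.entered] == oracle

    def test_constant_candidate_excluded_with_warning(self):
        rng = np.random.default_rng(13)
        df = self._frame(rng)
        df["meta_roi_cbf"] = 42.0
        with pytest.warns(UserWarning, match="constant"):
            res = stepwise_hierarchical(df, "cdr_sb")
        assert "meta_roi_cbf" not in [e[0] for e in res.entered]
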