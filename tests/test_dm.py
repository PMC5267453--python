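import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylpurity as mp
from methylpurity.dm import (
    arcsine_transform,
    build_design,
    call_dm,
    fit_site,
    shrink_variances,
    wald_test,
)

from conftest import truth_labels


def oracle_fit(z: np.ndarray, w: np.ndarray, n0: int, n1: int):
    """Independent explicit 2x2-inverse solution of the normal equation."""
    wtw = w.T @ w
    a, b, c, d = wtw[0, 0], wtw[0, 1], wtw[1, 0], wtw[1, 1]
    det = a * d - b * c
    inv = np.array([[d, -b], [-c, a]]) / det
    h = inv @ w.T
    beta = h @ z
    resid = z - w @ beta
    s2 = np.sum(resid[:n0] ** 2) / (n0 - 2)
    s2p = np.sum(resid[n0:] ** 2) / (n1 - 2)
    h1, h2 = h[:, :n0], h[:, n0:]
    var_beta = s2 * (h1 @ h1.T) + s2p * (h2 @ h2.T)
    return beta, var_beta


def random_design(rng, n0=None, n1=None):
    n0 = n0 or rng.integers(4, 20)
    n1 = n1 or rng.integers(4, 20)
    lam = rng.uniform(0.1, 1.0, n1)
    w = np.zeros((n0 + n1, 2))
    w[:, 0] = 1.0
    w[n0:, 1] = lam
    return w, int(n0), int(n1)


class TestArcsineTransform:
    @pytest.mark.parametrize(
        "v, expected",
        [(0.5, 0.0), (1.0, np.pi / 2), (0.0, -np.pi / 2), (0.75, np.pi / 6)],
    )
    def test_closed_form_values(self, v, expected):
        assert arcsine_transform([v])[0] == pytest.approx(expected, abs=1e-12)

    def test_inverse_round_trip(self):
        v = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            mp.dm.inverse_arcsine(arcsine_transform(v)), v, atol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="arcsine"):
            arcsine_transform([1.1])


class TestBuildDesign:
    def test_definitional_layout(self):
        groups = mp.SampleGroups(tumor_ids=["T1", "T2"], normal_ids=["N1", "N2"])
        pt = mp.PurityTable(pd.Series({"T1": 0.5, "T2": 0.8}))
        w, order = build_design(groups, pt)
        np.testing.assert_allclose(w, [[1, 0], [1, 0], [1, 0.5], [1, 0.8]])
        assert order == ["N1", "N2", "T1", "T2"]

    def test_unit_purity_reduces_to_group_indicator(self):
        groups = mp.SampleGroups(tumor_ids=["T1", "T2"], normal_ids=["N1"])
        pt = mp.PurityTable(pd.Series({"T1": 1.0, "T2": 1.0}))
        w, _ = build_design(groups, pt)
        np.testing.assert_array_equal(w[:, 1], [0, 1, 1])

    def test_missing_purity_names_sample(self):
        groups = mp.SampleGroups(tumor_ids=["T1", "T2"], normal_ids=["N1"])
        pt = mp.PurityTable(pd.Series({"T1": 0.5}))
        with pytest.raises(KeyError, match="T2"):
            build_design(groups, pt)


class TestFitSite:
    def test_exact_fit_with_unit_purity(self):
        n0 = n1 = 4
        w = np.zeros((8, 2))
        w[:, 0] = 1.0
        w[n0:, 1] = 1.0
        z = np.array([0.0] * 4 + [0.4] * 4)
        fit = fit_site(z, w, n0, n1)
        assert fit.m_hat[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.mu_hat[0] == pytest.approx(0.4, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            w, n0, n1 = random_design(rng)
            z = rng.normal(size=n0 + n1)
            fit = fit_site(z, w, n0, n1)
            beta_o, var_o = oracle_fit(z, w, n0, n1)
            np.testing.assert_allclose([fit.m_hat[0], fit.mu_hat[0]], beta_o, rtol=1e-10)
            np.testing.assert_allclose(fit.se_mu()[0], np.sqrt(var_o[1, 1]), rtol=1e-10)

    def test_constant_purity_noiseless_difference(self):
        # with all lambda = l0 and noiseless z, mu-hat is the pure-scale
        # difference d and the fitted tumor mean sits l0*d above m-hat
        l0, d, m = 0.6, 0.5, -0.2
        n0 = n1 = 5
        w = np.zeros((10, 2))
        w[:, 0] = 1.0
        w[n0:, 1] = l0
        z = np.array([m] * n0 + [m + l0 * d] * n1)
        fit = fit_site(z, w, n0, n1)
        assert fit.mu_hat[0] == pytest.approx(d, abs=1e-12)
        assert fit.m_hat[0] == pytest.approx(m, abs=1e-12)

    def test_small_groups_rejected(self):
        w = np.ones((4, 2))
        with pytest.raises(ValueError, match="n0 > 2"):
            fit_site(np.zeros(4), w, 2, 2)

    def test_multiplicative_effect_identity(self):
        # rescaling the purity column by k rescales mu-hat by exactly 1/k
        rng = np.random.default_rng(42)
        w, n0, n1 = random_design(rng, n0=6, n1=8)
        z = rng.normal(size=n0 + n1)
        k = 0.5
        w_scaled = w.copy()
        w_scaled[:, 1] *= k
        mu = fit_site(z, w, n0, n1).mu_hat[0]
        mu_scaled = fit_site(z, w_scaled, n0, n1).mu_hat[0]
        assert mu_scaled == pytest.approx(mu / k, rel=1e-12)


class TestShrinkVariances:
    def test_zero_weight_is_identity(self):
        v = np.array([0.3, 1.2, 0.7])
        np.testing.assert_allclose(shrink_variances(v, 0.0), v, rtol=1e-14)

    def test_full_weight_collapses_to_geometric_mean(self):
        v = np.array([0.5, 2.0, 8.0])
        gm = np.exp(np.mean(np.log(v)))
        np.testing.assert_allclose(shrink_variances(v, 1.0), gm, rtol=1e-12)

    def test_half_weight_closed_form(self):
        out = shrink_variances(np.array([1.0, 4.0]), 0.5)
        np.testing.assert_allclose(out, [np.sqrt(2.0), 2.0 * np.sqrt(2.0)], rtol=1e-12)

    def test_geometric_mean_preserved_for_all_weights(self):
        rng = np.random.default_rng(43)
        v = rng.lognormal(size=50)
        gm = np.exp(np.mean(np.log(v)))
        for w in (0.0, 0.2, 0.5, 0.9, 1.0):
            out = shrink_variances(v, w)
            assert np.exp(np.mean(np.log(out))) == pytest.approx(gm, rel=1e-10)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            shrink_variances(np.array([1.0]), 1.5)


class TestWaldTest:
    def test_zero_effect_gives_p_one(self):
        t, p = wald_test(np.array([0.0]), np.array([0.1]), 5, 7)
        assert (t[0], p[0]) == (0.0, 1.0)

    def test_t_reference_distribution(self):
        # 2 * (1 - F_t(2.0; df=10)) = 0.07339; frozen from the t CDF
        t, p = wald_test(np.array([0.2]), np.array([0.1]), 6, 6)
        assert t[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(0.07339, abs=5e-5)

    def test_degenerate_se_follows_sign_convention(self):
        t, p = wald_test(np.array([0.0, 0.3]), np.array([0.0, 0.0]), 5, 5)
        assert p[0] == 1.0
        assert p[1] == 0.0


class TestCallDm:
    def test_type_one_error_in_binomial_band(self, null_dataset):
        beta, groups, truth = null_dataset
        res = call_dm(beta, groups, mp.PurityTable(truth.purity))
        rate = (res["p"] < 0.05).mean()
        half_band = 2.576 * np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) <= half_band

    def test_null_bh_calls_near_expectation(self, null_dataset):
        beta, groups, truth = null_dataset
        res = call_dm(beta, groups, mp.PurityTable(truth.purity))
        # under the global null BH controls FWER at the q level:
        # P(any call) <= 0.05, so a handful of calls is already extreme
        assert (res["fdr"] < 0.05).sum() <= 5

    def test_fdr_control_and_power_vs_naive_t(self, dm_dataset):
        beta, groups, truth = dm_dataset
        res = call_dm(beta, groups, mp.PurityTable(truth.purity))
        is_dmc = truth_labels(res, truth)
        calls = (res["fdr"] < 0.05).to_numpy()
        observed_fdr = (~is_dmc[calls]).mean()
        assert observed_fdr <= 0.10
        sens_aware = (calls & is_dmc).sum() / is_dmc.sum()

        z = arcsine_transform(beta.subset_samples(
            groups.normal_ids + groups.tumor_ids).to_numpy())
        n0 = groups.n_normal
        _, p_naive = stats.ttest_ind(z[:, n0:], z[:, :n0], axis=1)

        def sens_at_matched_fdr(p, q=0.05):
            order = np.argsort(p)
            labels = is_dmc[order]
            tp = np.cumsum(labels)
            fp = np.cumsum(~labels)
            ok = fp / np.maximum(fp + tp, 1) <= q
            return (tp[ok].max() if ok.any() else 0) / is_dmc.sum()

        assert sens_at_matched_fdr(res["p"].to_numpy()) > sens_at_matched_fdr(p_naive)
        assert sens_aware > 0.5

    def test_unit_purity_reduces_to_heteroscedastic_two_group(self, null_dataset):
        beta, groups, truth = null_dataset
        ones = mp.PurityTable(pd.Series(1.0, index=groups.tumor_ids))
        res = call_dm(beta, groups, ones, shrink_weight=0.0)
        # independent two-group computation from the same model: with an
        # indicator design, mu-hat is the mean difference and
        # var(mu-hat) = s2/n0 + s2'/n1 with the n-2 denominators
        z = arcsine_transform(
            beta.subset_samples(groups.normal_ids + groups.tumor_ids).to_numpy()
        )
        n0, n1 = groups.n_normal, groups.n_tumor
        zn, zt = z[:, :n0], z[:, n0:]
        mu = zt.mean(axis=1) - zn.mean(axis=1)
        s2 = ((zn - zn.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (n0 - 2)
        s2p = ((zt - zt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (n1 - 2)
        t_ref = mu / np.sqrt(s2 / n0 + s2p / n1)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, rtol=1e-8)

    def test_fdr_monotone_and_order_invariant(self, dm_dataset):
        beta, groups, truth = dm_dataset
        res = call_dm(beta, groups, mp.PurityTable(truth.purity))
        by_p = res.sort_values("p")
        assert (np.diff(by_p["fdr"].to_numpy()) >= -1e-15).all()
        shuffled = mp.BetaMatrix(beta.values.sample(frac=1, random_state=9))
        res2 = call_dm(shuffled, groups, mp.PurityTable(truth.purity))
        merged = res.merge(res2, on="site_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["fdr_a"], merged["fdr_b"], rtol=1e-12)

    def test_missing_values_dropped(self, dm_dataset):
        beta, groups, truth = dm_dataset
        df = beta.values.copy()
        df.iloc[0, 0] = np.nan
        res = call_dm(mp.BetaMatrix(df), groups, mp.PurityTable(truth.purity))
        assert df.index[0] not in set(res["site_id"])
        assert len(res) == len(df) - 1
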