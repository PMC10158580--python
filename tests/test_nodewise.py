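"""Partial correlation, node-wise maps, and conjunction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tests.conftest import null_dataset, profile_matrix_from_array, single_tract_spec
from tractwise.nodewise import NodewiseResult, conjunction_nodes, nodewise_partial_map, partial_corr
from tractwise.simulate import EffectSpec, simulate_behavior, simulate_profiles


def brute_force_partial(x, y, Z):
    """Independent residualize-then-correlate oracle using polynomial fits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    Z = np.asarray(Z, float)
    if Z.size == 0:
        rx, ry = x - x.mean(), y - y.mean()
    else:
        D = np.column_stack([np.ones(len(x)), Z])
        rx = x - D @ np.linalg.pinv(D) @ x
        ry = y - D @ np.linalg.pinv(D) @ y
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    k = 0 if Z.size == 0 else Z.shape[1]
    df = len(x) - 2 - k
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    return r, df, 2 * stats.t.sf(abs(t), df)


class TestPartialCorr:
    def test_identity_and_reversal(self):
        r, df, p = partial_corr([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        r, _, _ = partial_corr([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_residualization_fixture(self):
        # frozen oracle: residuals of y on z are exactly the negation of the
        # residuals of x on z for this fixture, so the partial r is -1
        r, df, p = partial_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 6], [[1], [1], [2], [2], [3]])
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert df == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(8, 25))
            k = int(rng.integers(0, 3))
            x, y = rng.normal(size=n), rng.normal(size=n)
            Z = rng.normal(size=(n, k))
            r, df, p = partial_corr(x, y, Z if k else None)
            r0, df0, p0 = brute_force_partial(x, y, Z if k else np.empty((n, 0)))
            assert r == pytest.approx(r0, abs=1e-10)
            assert df == df0
            assert p == pytest.approx(p0, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(20):
            df_ = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("xyzw"))
            ours, dof, p = partial_corr(
                df_["x"], df_["y"], df_[["z", "w"]].to_numpy()
            )
            ref = pingouin.partial_corr(df_, x="x", y="y", covar=["z", "w"])
            assert ours == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_empty_covariates_equal_pearson_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, _, _ = partial_corr(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        r_swap, _, _ = partial_corr(y, x)
        assert r == pytest.approx(r_swap, abs=1e-14)

    def test_listwise_deletion(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6, 7])
        y = np.array([2.0, 4, 6, 8, np.nan, 12, 14])
        r, df, _ = partial_corr(x, y)
        assert r == pytest.approx(1.0)
        assert df == 5 - 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            partial_corr([1.0, 1, 1, 1, 1], [1.0, 2, 3, 4, 5])

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            partial_corr([1, 2], [3, 4])


class TestNodewiseMap:
    def test_self_correlation_is_one(self):
        c, pm = null_dataset(seed=1, n=20)
        k = 10
        c = c.copy()
        c["self"] = pm.data.iloc[:, k - 1].to_numpy()
        res = nodewise_partial_map(pm, "self", (), c)
        assert res.r[k - 1] == pytest.approx(1.0)
        assert res.n == 20 and res.df == 18

    def test_constant_n_across_nodes_with_missingness(self, cohort):
        spec = single_tract_spec(seed=2, n=35)
        c = simulate_behavior(spec, seed=2)
        c.loc[0, "en_read"] = np.nan
        pm = simulate_profiles(spec, c, seed=2)[0]
        res = nodewise_partial_map(pm, "en_read", ("age_years", "sex"), c)
        assert res.n == 34
        assert res.df == 34 - 2 - 2

    def test_null_p_values_uniform(self):
        # pooled over 50 null datasets with near-independent nodes
        ps = []
        for s in range(50):
            c, pm = null_dataset(seed=s, n=35, ell=0.5)
            res = nodewise_partial_map(pm, "cn_read", ("age_years", "sex"), c)
            ps.append(res.p)
        stat, pval = stats.kstest(np.concatenate(ps), "uniform")
        assert pval > 0.01

    def test_large_n_consistency_of_embedded_effect(self):
        spec = single_tract_spec(
            seed=0, n=200, effects=[EffectSpec("left_direct", 40, 60, "en_read", 0.55)]
        )
        c = simulate_behavior(spec)
        pm = simulate_profiles(spec, c)[0]
        res = nodewise_partial_map(pm, "en_read", ("age_years", "sex"), c)
        assert np.all(np.abs(res.r[44:55] - 0.55) < 0.1)

    def test_hard_error_when_too_few_subjects(self):
        c, pm = null_dataset(seed=3, n=35)
        tiny = c.iloc[:4]
        small = pm.data.iloc[:4]
        from tests.conftest import profile_matrix_from_array

        pm2 = profile_matrix_from_array(small.to_numpy(), ids=list(small.index))
        with pytest.raises(ValueError, match="left_direct"):
            nodewise_partial_map(pm2, "en_read", ("age_years", "sex"), tiny)


def fake_map(p, r, tract="left_direct"):
    p = np.asarray(p, float)
    r = np.asarray(r, float)
    return NodewiseResult(tract=tract, r=r, df=30, p=p, n=34)


class TestConjunction:
    def test_interval_intersection(self):
        n = 100
        pa, pb = np.ones(n), np.ones(n)
        pa[2:12] = 0.01   # nodes 3..12
        pb[7:20] = 0.01   # nodes 8..20
        a = fake_map(pa, np.ones(n))
        b = fake_map(pb, np.ones(n))
        np.testing.assert_array_equal(conjunction_nodes(a, b), np.arange(8, 13))

    def test_disjoint_sets_empty(self):
        n = 100
        pa, pb = np.ones(n), np.ones(n)
        pa[:5] = 0.01
        pb[50:55] = 0.01
        assert conjunction_nodes(fake_map(pa, np.ones(n)), fake_map(pb, np.ones(n))).size == 0

    def test_sign_disagreement_excluded(self):
        n = 100
        p = np.full(n, 0.01)
        ra, rb = np.ones(n), np.ones(n)
        rb[10:20] = -1.0
        nodes = conjunction_nodes(fake_map(p, ra), fake_map(p, rb))
        assert not np.isin(np.arange(11, 21), nodes).any()

    def test_commutative_and_idempotent(self):
        rng = np.random.default_rng(0)
        a = fake_map(rng.random(100), rng.normal(size=100))
        b = fake_map(rng.random(100), rng.normal(size=100))
        np.testing.assert_array_equal(conjunction_nodes(a, b), conjunction_nodes(b, a))
        np.testing.assert_array_equal(
            conjunction_nodes(a, a), a.significant_nodes(0.05)
        )

    def test_mismatched_tracts_rejected(self):
        a = fake_map(np.ones(100), np.ones(100), tract="left_direct")
        b = fake_map(np.ones(100), np.ones(100), tract="right_direct")
        with pytest.raises(ValueError, match="different tracts"):
            conjunction_nodes(a, b)

    def test_common_cluster_recovery(self):
        # both languages loaded on nodes 37-45: the conjunction should
        # overlap the true window in most seeds
        hits = 0
        for s in range(50):
            spec = single_tract_spec(
                seed=s, n=37,
                effects=[
                    EffectSpec("left_direct", 37, 45, "cn_read", 0.45),
                    EffectSpec("left_direct", 37, 45, "en_read", 0.45),
                ],
            )
            c = simulate_behavior(spec, seed=s)
            pm = simulate_profiles(spec, c, seed=s)[0]
            a = nodewise_partial_map(pm, "cn_read", ("age_years", "sex"), c)
            b = nodewise_partial_map(pm, "en_read", ("age_years", "sex"), c)
            nodes = conjunction_nodes(a, b)
            hits += np.isin(nodes, np.arange(37, 46)).any()
        assert hits / 50 >= 0.70
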