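import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcmeta.meta_odds import (
    ORResult,
    TwoByTwo,
    bh_adjust,
    dichotomize,
    feature_table,
    odds_ratio,
    pool_dl,
    pool_features,
    significant_features,
)
from crcmeta.synthetic import default_fecal_config, generate_collection


class TestDichotomize:
    def test_median_of_four(self):
        out = dichotomize([0.0, 0.0, 0.1, 0.2])
        assert out.tolist() == [False, False, True, True]

    def test_all_zeros_all_unexposed(self):
        assert not dichotomize([0.0, 0.0, 0.0]).any()

    def test_ties_at_median_unexposed(self):
        assert not dichotomize([0.3, 0.3, 0.3]).any()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            dichotomize([0.1])


class TestOddsRatio:
    def test_balanced_table(self):
        r = odds_ratio(TwoByTwo(10, 10, 10, 10))
        assert r.log_or == pytest.approx(0.0)
        assert r.se == pytest.approx(np.sqrt(0.4))
        assert r.ci95[0] == pytest.approx(0.2895, abs=2e-3)
        assert r.ci95[1] == pytest.approx(3.4541, abs=2e-3)
        assert not r.corrected

    def test_woolf_arithmetic(self):
        r = odds_ratio(TwoByTwo(20, 5, 10, 15))
        assert r.odds_ratio == pytest.approx(6.0)
        assert r.se == pytest.approx(0.6455, abs=1e-4)
        assert r.ci95[0] == pytest.approx(1.693, abs=2e-3)
        assert r.ci95[1] == pytest.approx(21.26, abs=2e-2)

    def test_haldane_correction(self):
        r = odds_ratio(TwoByTwo(5, 0, 3, 7))
        assert r.corrected
        assert r.odds_ratio == pytest.approx(5.5 * 7.5 / (0.5 * 3.5))

    def test_chisq_matches_scipy_uncorrected(self):
        from scipy.stats import chi2_contingency

        t = TwoByTwo(12, 5, 7, 20)
        r = odds_ratio(t)
        expected = chi2_contingency([[12, 5], [7, 20]], correction=False)[1]
        assert r.p_chisq == pytest.approx(expected)

    def test_empty_margin_excluded(self):
        assert odds_ratio(TwoByTwo(0, 0, 5, 5)) is None
        assert odds_ratio(TwoByTwo(5, 5, 0, 0)) is None

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            odds_ratio(TwoByTwo(0, 5, 0, 5))

    def test_ci_contains_point(self):
        r = odds_ratio(TwoByTwo(8, 3, 4, 9))
        assert r.ci95[0] < r.odds_ratio < r.ci95[1]

    @given(
        a=st.integers(0, 30),
        b=st.integers(0, 30),
        c=st.integers(0, 30),
        d=st.integers(0, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_transpose_antisymmetry(self, a, b, c, d):
        t = TwoByTwo(a, b, c, d)
        if t.n_cases == 0 or t.n_controls == 0:
            return
        r = odds_ratio(t)
        rt = odds_ratio(t.transpose_groups())
        if r is None:
            assert rt is None
        else:
            assert rt.log_or == pytest.approx(-r.log_or, abs=1e-12)


def _or(y, se):
    return ORResult(
        log_or=y, se=se, ci95=(0, 1), p_chisq=1.0, corrected=False,
        table=TwoByTwo(1, 1, 1, 1),
    )


class TestPoolDL:
    def test_homogeneous_duplicates(self):
        r = pool_dl({f"s{i}": _or(0.5, 0.2) for i in range(3)})
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.tau2 == 0.0

    def test_worked_example(self):
        r = pool_dl({"s1": _or(0.0, 0.5), "s2": _or(1.0, 0.5)})
        assert r.tau2 == pytest.approx(0.25)
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.pooled_se == pytest.approx(0.5)

    def test_convex_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ys = rng.normal(0, 1, 4)
            ses = rng.uniform(0.1, 1.0, 4)
            r = pool_dl({f"s{i}": _or(y, s) for i, (y, s) in enumerate(zip(ys, ses))})
            assert ys.min() - 1e-12 <= r.pooled_log_or <= ys.max() + 1e-12

    def test_equal_se_no_heterogeneity_is_mean(self):
        ys = [0.1, 0.12, 0.11]
        r = pool_dl({f"s{i}": _or(y, 1.0) for i, y in enumerate(ys)})
        assert r.tau2 == 0.0  # Q < k-1
        assert r.pooled_log_or == pytest.approx(np.mean(ys))

    def test_symbolic_k2_oracle(self):
        # direct evaluation of the DL formulas for arbitrary k=2 inputs
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.normal(0, 2, 2)
            se = rng.uniform(0.05, 2.0, 2)
            w = 1 / se**2
            yfe = (w * y).sum() / w.sum()
            q = (w * (y - yfe) ** 2).sum()
            tau2 = max(0.0, (q - 1) / (w.sum() - (w**2).sum() / w.sum()))
            ws = 1 / (se**2 + tau2)
            expected = (ws * y).sum() / ws.sum()
            r = pool_dl({"a": _or(y[0], se[0]), "b": _or(y[1], se[1])})
            assert r.pooled_log_or == pytest.approx(expected, rel=1e-12)
            assert r.tau2 == pytest.approx(tau2, rel=1e-12)

    def test_k1_skipped(self):
        assert pool_dl({"s1": _or(0.5, 0.2)}) is None


def bh_oracle(p):
    """Exhaustive min-over-suffix definition of BH step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1, 1, 1]), [1, 1, 1])

    def test_two_values(self):
        np.testing.assert_allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 40)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_oracle_and_monotonicity(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSignificantFeatures:
    def test_alpha_zero_empty(self):
        cfg = default_fecal_config(seed=0, n_taxa=40, scale=0.1)
        coll, _ = generate_collection(cfg)
        assert significant_features(coll, "carcinoma", alpha=0.0) == []

    def test_pooled_sign_flip_on_group_transpose(self, caplog):
        cfg = default_fecal_config(seed=5, n_taxa=40, scale=0.2)
        coll, _ = generate_collection(cfg)
        pooled = pool_features(coll, "carcinoma")
        flipped = {}
        for pr in pooled:
            res = {
                sid: odds_ratio(r.table.transpose_groups())
                for sid, r in pr.per_study.items()
            }
            flipped[pr.feature_id] = pool_dl(res)
        for pr in pooled:
            assert flipped[pr.feature_id].pooled_log_or == pytest.approx(
                -pr.pooled_log_or, abs=1e-10
            )

    def test_p_bh_at_least_p(self):
        cfg = default_fecal_config(seed=2, n_taxa=50, scale=0.2)
        coll, _ = generate_collection(cfg)
        pooled = pool_features(coll, "carcinoma")
        assert pooled
        for pr in pooled:
            assert pr.p_bh >= pr.p - 1e-15

    def test_absent_taxon_excluded_per_study(self):
        # a feature all-zero in one study yields a degenerate table there
        from .conftest import make_study
        from crcmeta.io import harmonize

        rng = np.random.default_rng(0)
        d = ["control"] * 6 + ["carcinoma"] * 6
        s1 = make_study(rng.integers(1, 50, (12, 3)), study_id="a", diagnoses=d,
                        feature_ids=["A", "B", "C"])
        s2 = make_study(rng.integers(1, 50, (12, 2)), study_id="b", diagnoses=d,
                        feature_ids=["A", "B"])
        s3 = make_study(rng.integers(1, 50, (12, 3)), study_id="c", diagnoses=d,
                        feature_ids=["A", "B", "C"])
        coll = harmonize([s1, s2, s3])
        pooled = {pr.feature_id: pr for pr in pool_features(coll, "carcinoma")}
        assert set(pooled["C"].per_study) <= {"a", "c"}
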