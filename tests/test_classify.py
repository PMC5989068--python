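import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcmeta.classify import (
    CVResult,
    auc,
    compare_models,
    cv_auc,
    mda_zscores,
    mtry,
    single_taxon_auc,
    study_significant_features,
    train_rf,
    transfer_evaluate,
)
from crcmeta.synthetic import (
    EnrichedTaxon,
    SyntheticConfig,
    default_fecal_config,
    generate_collection,
    generate_study,
)

from .conftest import make_study


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pair_enumeration_example(self):
        # cases (0.9, 0.4), controls (0.5, 0.1): 3 of 4 pairs correct
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=30).round(1)  # rounding makes ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    @given(
        scores=st.lists(
            st.floats(-5, 5).map(lambda v: round(v, 2)), min_size=4, max_size=20
        ),
        shift=st.floats(0.1, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_transform_invariance(self, scores, shift):
        # rounding keeps distinct scores distinguishable after exp()
        s = np.array(scores)
        labels = (np.arange(s.size) % 2).astype(bool)
        base = auc(s, labels)
        assert auc(np.exp(s / 5) * shift, labels) == pytest.approx(base, abs=1e-12)


class TestSingleTaxonAUC:
    def test_absent_feature_half(self):
        counts = np.ones((8, 3), dtype=int)
        counts[:, 2] = 0
        t = make_study(counts, diagnoses=["control"] * 4 + ["carcinoma"] * 4)
        assert single_taxon_auc(t, "T2", "carcinoma") == 0.5

    def test_patchy_taxon_weak_despite_or(self):
        # one enriched taxon, fold e^2 but patchy: median single-study AUC stays low
        aucs = []
        for seed in range(25):
            cfg = SyntheticConfig(
                n_studies=1,
                group_sizes=[(40, 0, 40)],
                n_taxa=40,
                seed=seed,
                enriched_taxa=[EnrichedTaxon(index=5, log_fold_change=2.0,
                                             patchiness=0.5)],
            )
            study = generate_study(cfg, 0)
            aucs.append(single_taxon_auc(study, study.feature_ids[5], "carcinoma"))
        assert np.median(aucs) < 0.72  # collectively predictive taxa are weak alone


class TestTrainRF:
    def test_mtry_floor_sqrt(self):
        assert mtry(1) == 1
        assert mtry(8) == 2
        assert mtry(200) == 14

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(40, 6))
        y = rng.integers(0, 2, 40)
        y[:3] = 0
        y[-3:] = 1
        p1 = train_rf(x, y, seed=7, n_estimators=50).predict_proba(x)
        p2 = train_rf(x, y, seed=7, n_estimators=50).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            train_rf(np.ones((5, 2)), np.zeros(5))


class TestCVAUC:
    def test_weir_rule_fallback(self, caplog):
        cfg = SyntheticConfig(
            n_studies=1, group_sizes=[(4, 0, 7)], n_taxa=20, seed=0
        )
        study = generate_study(cfg, 0)
        with caplog.at_level("WARNING", logger="crcmeta"):
            r = cv_auc(study, study.feature_ids, "carcinoma", k=10,
                       n_estimators=30)
        assert r.k == 2
        assert "falling back to k=2" in caplog.text

    def test_too_few_samples_errors(self):
        t = make_study(
            np.ones((3, 4), dtype=int),
            diagnoses=["control", "control", "carcinoma"],
        )
        with pytest.raises(ValueError, match=">=2 samples per class"):
            cv_auc(t, t.feature_ids, "carcinoma")

    def test_strong_signal_high_auc(self):
        cfg = SyntheticConfig(
            n_studies=1, group_sizes=[(100, 0, 100)], n_taxa=50, seed=1,
            enriched_taxa=[
                EnrichedTaxon(index=i, log_fold_change=2.5) for i in range(4)
            ],
        )
        study = generate_study(cfg, 0)
        r = cv_auc(study, study.feature_ids, "carcinoma", k=10, seed=0,
                   n_estimators=200, importance_repeats=1)
        assert r.auc >= 0.9

    def test_repeats_recorded(self):
        cfg = SyntheticConfig(
            n_studies=1, group_sizes=[(20, 0, 20)], n_taxa=15, seed=0
        )
        study = generate_study(cfg, 0)
        r = cv_auc(study, study.feature_ids, "carcinoma", k=3, repeats=4,
                   seed=0, n_estimators=30, importance_repeats=1)
        assert len(r.per_repeat) == 4
        assert r.auc == pytest.approx(np.mean(r.per_repeat))

    def test_label_shuffle_near_half(self):
        aucs = []
        for seed in range(10):
            cfg = SyntheticConfig(
                n_studies=1, group_sizes=[(30, 0, 30)], n_taxa=25, seed=seed
            )
            study = generate_study(cfg, 0)
            r = cv_auc(study, study.feature_ids, "carcinoma", k=5, seed=seed,
                       n_estimators=50, importance_repeats=1)
            aucs.append(r.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1


class TestMDAZscores:
    def _cv(self, study_id, importances):
        return CVResult(
            study_id=study_id, regime="all_taxa", auc=0.7, per_repeat=[0.7],
            importances=importances, k=10,
        )

    def test_single_study_preserves_order(self):
        r = self._cv("a", {"x": 0.3, "y": 0.1, "z": 0.2})
        ranking = mda_zscores([r])
        assert list(ranking.index) == ["x", "z", "y"]

    def test_consistent_top_feature_ranks_first(self):
        rs = [
            self._cv("a", {"x": 0.5, "y": 0.1, "z": 0.05}),
            self._cv("b", {"x": 0.4, "y": 0.02, "z": 0.2}),
            self._cv("c", {"x": 0.6, "y": 0.3, "z": 0.1}),
        ]
        ranking = mda_zscores(rs)
        assert ranking.index[0] == "x"
        assert ranking.loc["x", "rank"] == 1

    def test_consistent_protective_outranks_patchy_enriched(self):
        # patchy enriched taxa carry signal only when present; consistently
        # shifted protective taxa end up more important across studies
        from crcmeta.synthetic import ProtectiveTaxon

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                n_studies=4, group_sizes=[(40, 0, 40)] * 4, n_taxa=30,
                seed=seed,
                enriched_taxa=[
                    EnrichedTaxon(index=i, log_fold_change=1.2, patchiness=0.5)
                    for i in (3, 4)
                ],
                protective_taxa=[
                    ProtectiveTaxon(index=i, log_fold_change=-1.2)
                    for i in (6, 7)
                ],
            )
            coll, truth = generate_collection(cfg)
            feats = [truth.feature_ids[i] for i in (3, 4, 6, 7)]
            results = [
                cv_auc(s, feats, "carcinoma", k=5, seed=seed, n_estimators=80,
                       importance_repeats=8)
                for s in coll.studies
            ]
            mz = mda_zscores(results)["mean_z"]
            prot = np.mean([mz[truth.feature_ids[i]] for i in (6, 7)])
            enr = np.mean([mz[truth.feature_ids[i]] for i in (3, 4)])
            wins += prot > enr
        assert wins >= int(0.8 * n_seeds)

    def test_constant_vector_skipped(self, caplog):
        rs = [
            self._cv("a", {"x": 0.2, "y": 0.2}),
            self._cv("b", {"x": 0.5, "y": 0.1}),
        ]
        with caplog.at_level("WARNING", logger="crcmeta"):
            ranking = mda_zscores(rs)
        assert "constant MDA" in caplog.text
        assert ranking.loc["x", "n_studies"] == 1


class TestCompareModels:
    def test_identical_vectors_convention(self):
        r = compare_models([0.7, 0.8, 0.6], [0.7, 0.8, 0.6])
        assert r.t == 0.0 and r.p == 0.5

    def test_constant_positive_difference_degenerate(self):
        r = compare_models([0.8, 0.7, 0.6], [0.7, 0.6, 0.5])
        assert r.degenerate and r.p == 0.0
        assert r.mean_diff == pytest.approx(0.1)

    def test_length_errors(self):
        with pytest.raises(ValueError):
            compare_models([0.7, 0.8], [0.6, 0.7])

    def test_matches_scipy_one_tailed(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 0.9, 7)
        b = a - rng.normal(0.05, 0.03, 7)
        r = compare_models(a, b)
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert r.p == pytest.approx(ref.pvalue)

    def test_power_matches_analytic(self):
        # d_i ~ N(mu, sd): rejection rate of the one-tailed paired t at
        # alpha=0.05 should match the noncentral-t power within binomial CI
        from scipy import stats

        mu, sd, n, n_sim = 0.05, 0.06, 7, 400
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(n_sim):
            b = rng.uniform(0.5, 0.8, n)
            a = b + rng.normal(mu, sd, n)
            if compare_models(a, b).p < 0.05:
                rejections += 1
        nc = mu / (sd / np.sqrt(n))
        crit = stats.t.ppf(0.95, n - 1)
        power = 1 - stats.nct.cdf(crit, n - 1, nc)
        se = np.sqrt(power * (1 - power) / n_sim)
        assert abs(rejections / n_sim - power) <= 3.5 * se


class TestTransfer:
    def _collection(self, seed, strong=True, n=40):
        enriched = (
            [EnrichedTaxon(index=i, log_fold_change=1.5, patchiness=0.2)
             for i in range(3)]
            if strong
            else []
        )
        cfg = SyntheticConfig(
            n_studies=3,
            group_sizes=[(n, 0, n)] * 3,
            n_taxa=30,
            seed=seed,
            enriched_taxa=enriched,
            study_effect_sd=0.5,
        )
        return generate_collection(cfg)[0]

    def test_shared_signal_transfers(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            coll = self._collection(seed)
            tm = transfer_evaluate(
                coll, "all_taxa", "carcinoma", seed=seed, n_estimators=50,
                compute_diagonal=False,
            )
            off = tm.auc[~np.eye(3, dtype=bool)]
            if np.nanmean(off) > 0.5:
                wins += 1
        assert wins >= 9

    def test_null_transfer_near_half(self):
        vals = []
        for seed in range(8):
            coll = self._collection(seed, strong=False)
            tm = transfer_evaluate(
                coll, "all_taxa", "carcinoma", seed=seed, n_estimators=50,
                compute_diagonal=False,
            )
            vals.append(np.nanmean(tm.auc[~np.eye(3, dtype=bool)]))
        assert abs(np.mean(vals) - 0.5) <= 0.1

    def test_matrix_shape(self):
        coll = self._collection(0)
        tm = transfer_evaluate(
            coll, "all_taxa", "carcinoma", seed=0, n_estimators=30, cv_k=2
        )
        assert tm.auc.shape == (3, 3)
        off_diag = tm.auc[~np.eye(3, dtype=bool)]
        assert np.isfinite(off_diag).sum() == 6
        assert np.isfinite(np.diag(tm.auc)).all()

    def test_study_significant_features_on_signal(self):
        cfg = SyntheticConfig(
            n_studies=1, group_sizes=[(120, 0, 120)], n_taxa=40, seed=3,
            enriched_taxa=[EnrichedTaxon(index=2, log_fold_change=2.0)],
        )
        study = generate_study(cfg, 0)
        feats = study_significant_features(study, "carcinoma")
        assert study.feature_ids[2] in feats
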