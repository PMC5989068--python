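"""Random-forest classification of diagnosis within and across studies.

Forests use 500 trees and mtry = floor(sqrt(p)) candidate features per
split. Cross-validated AUC comes from out-of-fold class probabilities
pooled across folds (one ROC per repeat); importances are permutation
mean-decrease-in-accuracy from a final fit on all samples. Transfer
evaluation trains on one study and scores every other study, with
feature selection restricted to the training study to avoid test-study
leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from crcmeta.io import MetaCollection, StudyTable, to_relative_abundance
from crcmeta.meta_odds import (
    bh_adjust,
    dichotomize,
    feature_table,
    odds_ratio,
    significant_features,
)

logger = logging.getLogger("crcmeta")

REGIMES = ("sig_or_taxa", "all_taxa", "otu")

NTREE = 500


@dataclass(frozen=True)
class FoldScheme:
    k: int
    stratified: bool = True
    seed: int = 0

    def assignment(self, labels: np.ndarray) -> np.ndarray:
        """Fold index per sample (stratified, seeded, shuffled)."""
        labels = np.asarray(labels)
        splitter = StratifiedKFold(
            n_splits=self.k, shuffle=True, random_state=self.seed
        )
        folds = np.empty(labels.size, dtype=int)
        dummy = np.zeros((labels.size, 1))
        for f, (_, test_idx) in enumerate(splitter.split(dummy, labels)):
            folds[test_idx] = f
        return folds


@dataclass
class CVResult:
    study_id: str
    regime: str
    auc: float
    per_repeat: list[float]
    importances: dict[str, float]
    k: int
    comparison: str = "carcinoma"


@dataclass
class TransferMatrix:
    study_ids: list[str]
    regime: str
    auc: np.ndarray  # train x test; NaN where not applicable
    features_used: dict[str, list[str]] = field(default_factory=dict)

    def median_test_auc(self) -> pd.Series:
        """Median off-diagonal AUC per training study."""
        vals = {}
        for i, sid in enumerate(self.study_ids):
            row = np.delete(self.auc[i], i)
            row = row[np.isfinite(row)]
            vals[sid] = float(np.median(row)) if row.size else np.nan
        return pd.Series(vals, name="median_test_auc")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.auc, index=self.study_ids, columns=self.study_ids
        ).rename_axis("train_study")


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Orientation: higher score means case (label 1/True).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r1 = ranks[labels].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def single_taxon_auc(
    study: StudyTable, feature_id: str, comparison: str
) -> float:
    """AUC of one feature's relative abundance as a raw (unoriented) score."""
    sub = study.comparison_subset(comparison)
    d = sub.diagnoses()
    if (d == comparison).sum() == 0 or (d == "control").sum() == 0:
        raise ValueError(
            f"study {study.study_id}: empty group for comparison {comparison}"
        )
    ra = to_relative_abundance(sub)
    j = sub.feature_ids.index(feature_id)
    scores = ra[:, j]
    if np.ptp(scores) == 0:
        return 0.5
    return auc(scores, d == comparison)


# ---------------------------------------------------------------------------
# Forests
# ---------------------------------------------------------------------------

def mtry(p: int) -> int:
    return max(1, int(np.floor(np.sqrt(p))))


def train_rf(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = NTREE,
) -> RandomForestClassifier:
    """Fit a seeded forest: ``n_estimators`` bootstrap trees, mtry=floor(sqrt(p))."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError("features must be a samples x p matrix with p >= 1")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=mtry(features.shape[1]),
        bootstrap=True,
        random_state=seed,
    )
    clf.fit(features, labels)
    return clf


def mda_importances(
    clf: RandomForestClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Permutation mean-decrease-in-accuracy per feature."""
    imp = permutation_importance(
        clf,
        features,
        labels,
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return dict(zip(feature_ids, imp.importances_mean.astype(float)))


def _case_matrix(
    study: StudyTable, feature_ids: list[str], comparison: str
) -> tuple[np.ndarray, np.ndarray]:
    """Relative-abundance matrix over the given features (zero-filled for
    features outside the study namespace) and binary case labels."""
    sub = study.comparison_subset(comparison)
    ra = to_relative_abundance(sub)
    pos = {f: j for j, f in enumerate(sub.feature_ids)}
    x = np.zeros((sub.n_samples, len(feature_ids)))
    for j, f in enumerate(feature_ids):
        if f in pos:
            x[:, j] = ra[:, pos[f]]
    y = (sub.diagnoses() == comparison).astype(int)
    return x, y


def cv_auc(
    study: StudyTable,
    feature_ids: list[str],
    comparison: str,
    regime: str = "all_taxa",
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    n_estimators: int = NTREE,
    importance_repeats: int = 10,
) -> CVResult:
    """Repeated stratified k-fold CV AUC from pooled out-of-fold probabilities.

    When k exceeds the smallest class size the scheme falls back to k=2
    (logged), mirroring small-cohort practice.
    """
    x, y = _case_matrix(study, feature_ids, comparison)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"study {study.study_id}: need >=2 samples per class, "
            f"got {n0} controls / {n1} cases"
        )
    if k > min(n0, n1):
        logger.warning(
            "study %s: %d-fold CV infeasible (min class %d); falling back to k=2",
            study.study_id,
            k,
            min(n0, n1),
        )
        k = 2
    per_repeat = []
    for r in range(repeats):
        scheme = FoldScheme(k=k, seed=seed + r)
        folds = scheme.assignment(y)
        oof = np.empty(y.size)
        for f in range(k):
            test = folds == f
            clf = train_rf(
                x[~test], y[~test], seed=seed + 1000 * r + f,
                n_estimators=n_estimators,
            )
            case_col = list(clf.classes_).index(1)
            oof[test] = clf.predict_proba(x[test])[:, case_col]
        per_repeat.append(auc(oof, y == 1))
    final = train_rf(x, y, seed=seed, n_estimators=n_estimators)
    importances = mda_importances(
        final, x, y, feature_ids, seed=seed, n_repeats=importance_repeats
    )
    return CVResult(
        study_id=study.study_id,
        regime=regime,
        auc=float(np.mean(per_repeat)),
        per_repeat=per_repeat,
        importances=importances,
        k=k,
        comparison=comparison,
    )


def mda_zscores(cv_results: list[CVResult]) -> pd.DataFrame:
    """Cross-study feature ranking by mean Z-scored MDA.

    MDA vectors are Z-scored within each study (constant vectors skipped
    with a warning); features are ranked by the mean Z over studies where
    they appear.
    """
    if not cv_results:
        raise ValueError("no CV results to rank")
    cols = {}
    for r in cv_results:
        vals = pd.Series(r.importances, dtype=float)
        if vals.std(ddof=1) == 0 or not np.isfinite(vals.std(ddof=1)):
            logger.warning(
                "study %s: constant MDA vector; skipped for Z-ranking", r.study_id
            )
            continue
        cols[r.study_id] = (vals - vals.mean()) / vals.std(ddof=1)
    if not cols:
        raise ValueError("no usable MDA vectors (all constant)")
    z = pd.DataFrame(cols)
    out = pd.DataFrame(
        {
            "mean_z": z.mean(axis=1, skipna=True),
            "n_studies": z.notna().sum(axis=1),
        }
    )
    out = out.sort_values("mean_z", ascending=False)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.index.name = "feature"
    return out


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedComparison:
    t: float
    p: float
    mean_diff: float
    mean_percent_diff: float
    degenerate: bool = False


def compare_models(
    aucs_a: np.ndarray, aucs_b: np.ndarray
) -> PairedComparison:
    """One-tailed paired t test of mean(a - b) > 0, paired by study.

    Identical vectors give t=0, p=0.5 by convention; a constant nonzero
    difference (zero variance) is flagged degenerate with p at the
    appropriate limit.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    d = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = float(np.mean(d / b)) * 100.0
    if np.allclose(d, 0.0, atol=1e-12):
        return PairedComparison(t=0.0, p=0.5, mean_diff=0.0, mean_percent_diff=0.0)
    if np.allclose(d, d.mean(), atol=1e-12):
        p = 0.0 if d.mean() > 0 else 1.0
        return PairedComparison(
            t=float(np.inf if d.mean() > 0 else -np.inf),
            p=p,
            mean_diff=float(d.mean()),
            mean_percent_diff=pct,
            degenerate=True,
        )
    res = stats.ttest_rel(a, b, alternative="greater")
    return PairedComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
        mean_percent_diff=pct,
    )


# ---------------------------------------------------------------------------
# Transfer
# ---------------------------------------------------------------------------

def study_significant_features(
    study: StudyTable, comparison: str, alpha: float = 0.05
) -> list[str]:
    """Features with BH-significant median-dichotomized ORs within one study.

    Used for leakage-free feature selection in transfer mode, where only
    the training study may inform the feature set (single-study selection
    uses the per-study chi-square p since pooling needs >=2 studies).
    """
    sub = study.comparison_subset(comparison)
    ra = to_relative_abundance(sub)
    is_case = sub.diagnoses() == comparison
    feats, pvals = [], []
    med = np.median(ra, axis=0)
    exposed = ra > med[None, :]
    for j, f in enumerate(sub.feature_ids):
        res = odds_ratio(feature_table(exposed[:, j], is_case))
        if res is not None and np.isfinite(res.p_chisq):
            feats.append(f)
            pvals.append(res.p_chisq)
    if not feats:
        return []
    adj = bh_adjust(np.array(pvals))
    return [f for f, pa in zip(feats, adj) if pa < alpha]


def transfer_evaluate(
    collection: MetaCollection,
    regime: str,
    comparison: str,
    seed: int = 0,
    alpha: float = 0.05,
    n_estimators: int = NTREE,
    cv_k: int = 10,
    compute_diagonal: bool = True,
) -> TransferMatrix:
    """Train on each study, test on every other; diagonal is the training
    study's own CV AUC (NaN when ``compute_diagonal`` is off). Cells where
    the test study lacks a class are NaN.
    """
    if regime not in ("sig_or_taxa", "all_taxa"):
        raise ValueError("transfer supports regimes 'sig_or_taxa' and 'all_taxa'")
    usable = []
    for s in collection.studies:
        d = s.diagnoses()
        if (d == comparison).sum() >= 2 and (d == "control").sum() >= 2:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError("need >=2 studies with both classes for transfer")
    ids = [s.study_id for s in usable]
    k_all = len(ids)
    grid = np.full((k_all, k_all), np.nan)
    features_used: dict[str, list[str]] = {}
    for i, train in enumerate(usable):
        if regime == "all_taxa":
            feats = list(collection.feature_union)
        else:
            feats = study_significant_features(train, comparison, alpha=alpha)
            if not feats:
                logger.warning(
                    "study %s: no significant features; transfer row skipped",
                    train.study_id,
                )
                continue
        features_used[train.study_id] = feats
        x_tr, y_tr = _case_matrix(train, feats, comparison)
        clf = train_rf(x_tr, y_tr, seed=seed + i, n_estimators=n_estimators)
        case_col = list(clf.classes_).index(1)
        for j, test in enumerate(usable):
            if i == j:
                if not compute_diagonal:
                    continue
                grid[i, j] = cv_auc(
                    train,
                    feats,
                    comparison,
                    regime=regime,
                    k=cv_k,
                    seed=seed + i,
                    n_estimators=n_estimators,
                    importance_repeats=1,
                ).auc
                continue
            x_te, y_te = _case_matrix(test, feats, comparison)
            scores = clf.predict_proba(x_te)[:, case_col]
            grid[i, j] = auc(scores, y_te == 1)
    return TransferMatrix(
        study_ids=ids, regime=regime, auc=grid, features_used=features_used
    )


def regime_features(
    collection: MetaCollection, regime: str, comparison: str, alpha: float = 0.05
) -> list[str]:
    """Feature namespace for a regime in within-study CV mode."""
    if regime == "all_taxa":
        return list(collection.feature_union)
    if regime == "sig_or_taxa":
        return [
            pr.feature_id
            for pr in significant_features(collection, comparison, alpha=alpha)
        ]
    if regime == "otu":
        return list(collection.feature_union)
    raise ValueError(f"unknown regime {regime!r}")
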