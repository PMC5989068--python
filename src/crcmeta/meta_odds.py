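"""Per-taxon median-dichotomized odds ratios pooled across studies.

For each feature within each study: samples are split at the study-wide
median relative abundance (strictly greater than the median = exposed;
ties fall below), a 2x2 case/control table is formed, and a Woolf-interval
odds ratio with a chi-square test is computed. Per-feature log odds
ratios are pooled across studies with the DerSimonian-Laird random-effects
estimator, and the pooled Wald p values are Benjamini-Hochberg corrected
within each (site, comparison) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from crcmeta.io import MetaCollection, StudyTable, to_relative_abundance

logger = logging.getLogger("crcmeta")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """a: exposed cases, b: exposed controls, c: unexposed cases,
    d: unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    def transpose_groups(self) -> "TwoByTwo":
        """Swap case and control columns (maps log-OR to its negative)."""
        return TwoByTwo(a=self.b, b=self.a, c=self.d, d=self.c)


@dataclass(frozen=True)
class ORResult:
    log_or: float
    se: float
    ci95: tuple[float, float]
    p_chisq: float
    corrected: bool  # Haldane-Anscombe 0.5 applied
    table: TwoByTwo

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))


@dataclass
class PooledOR:
    feature_id: str
    per_study: dict[str, ORResult]
    k: int
    pooled_log_or: float
    pooled_se: float
    tau2: float
    ci95: tuple[float, float]
    p: float
    p_bh: float = float("nan")
    significant: bool = False

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_log_or))


def dichotomize(values: np.ndarray) -> np.ndarray:
    """Exposure indicator: strictly greater than the median over all the
    included samples; ties at the median count as unexposed."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    return values > np.median(values)


def odds_ratio(t: TwoByTwo) -> ORResult | None:
    """Woolf-interval odds ratio with chi-square p.

    When any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) before the OR/SE/CI; the chi-square is always on
    the uncorrected table and uses no continuity correction. Tables with
    an empty exposure margin (a+b = 0 or c+d = 0) are degenerate: the
    feature carries no exposure split, so ``None`` (an exclusion marker)
    is returned instead of a number.
    """
    if t.n_cases < 1 or t.n_controls < 1:
        raise ValueError("both groups must be non-empty")
    if (t.a + t.b) == 0 or (t.c + t.d) == 0:
        return None
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    # log(ad) - log(bc) rather than log(ad/bc): exactly antisymmetric
    # under case/control transposition in floating point
    log_or = float(np.log(a * d) - np.log(b * c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    ci = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return ORResult(
        log_or=log_or, se=se, ci95=ci, p_chisq=float(p), corrected=corrected, table=t
    )


def feature_table(
    exposed: np.ndarray, is_case: np.ndarray
) -> TwoByTwo:
    """Build the 2x2 from exposure and case indicators."""
    exposed = np.asarray(exposed, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    return TwoByTwo(
        a=int(np.sum(exposed & is_case)),
        b=int(np.sum(exposed & ~is_case)),
        c=int(np.sum(~exposed & is_case)),
        d=int(np.sum(~exposed & ~is_case)),
    )


def study_feature_or(
    study: StudyTable, feature_id: str, comparison: str
) -> ORResult | None:
    """Median-dichotomized OR for one feature in one study, or None if the
    table is degenerate / a group is empty."""
    sub = study.comparison_subset(comparison)
    d = sub.diagnoses()
    if (d == comparison).sum() == 0 or (d == "control").sum() == 0:
        return None
    ra = to_relative_abundance(sub)
    j = sub.feature_ids.index(feature_id)
    exposed = dichotomize(ra[:, j])
    return odds_ratio(feature_table(exposed, d == comparison))


def pool_dl(results: dict[str, ORResult]) -> PooledOR | None:
    """DerSimonian-Laird random-effects pooling of per-study log-ORs.

    Returns None when fewer than 2 eligible studies are available.
    """
    if len(results) < 2:
        return None
    y = np.array([r.log_or for r in results.values()])
    se = np.array([r.se for r in results.values()])
    k = len(y)
    w = 1.0 / se**2
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (
        float(np.exp(pooled - Z95 * pooled_se)),
        float(np.exp(pooled + Z95 * pooled_se)),
    )
    return PooledOR(
        feature_id="",
        per_study=dict(results),
        k=k,
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        tau2=tau2,
        ci95=ci,
        p=p,
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pool_features(
    collection: MetaCollection,
    comparison: str,
    alpha: float = 0.05,
    min_studies: int = 2,
) -> list[PooledOR]:
    """Per-feature dichotomized ORs pooled across studies, BH-corrected.

    A feature must yield a non-degenerate 2x2 in at least ``min_studies``
    studies to be pooled; others are skipped (logged).
    """
    if collection.feature_level != "taxon":
        raise ValueError("pooling requires a harmonized taxon-level collection")
    per_feature: dict[str, dict[str, ORResult]] = {
        f: {} for f in collection.feature_union
    }
    for study in collection.studies:
        d_all = study.diagnoses()
        n_case = int((d_all == comparison).sum())
        n_ctrl = int((d_all == "control").sum())
        if n_case == 0 or n_ctrl == 0:
            logger.info(
                "study %s skipped for %s ORs (empty group)",
                study.study_id,
                comparison,
            )
            continue
        sub = study.comparison_subset(comparison)
        ra = to_relative_abundance(sub)
        is_case = sub.diagnoses() == comparison
        med = np.median(ra, axis=0)
        exposed = ra > med[None, :]
        for j, f in enumerate(sub.feature_ids):
            res = odds_ratio(feature_table(exposed[:, j], is_case))
            if res is not None:
                per_feature[f][study.study_id] = res

    pooled: list[PooledOR] = []
    for f, results in per_feature.items():
        if len(results) < min_studies:
            continue
        pr = pool_dl(results)
        if pr is None:
            continue
        pr.feature_id = f
        pooled.append(pr)
    skipped = len(per_feature) - len(pooled)
    if skipped:
        logger.info(
            "%d feature(s) ineligible for pooling (<%d usable studies)",
            skipped,
            min_studies,
        )
    if not pooled:
        logger.warning("no eligible features to pool for comparison %s", comparison)
        return []
    adj = bh_adjust(np.array([pr.p for pr in pooled]))
    for pr, pa in zip(pooled, adj):
        pr.p_bh = float(pa)
        pr.significant = bool(pa < alpha)
    return pooled


def significant_features(
    collection: MetaCollection,
    comparison: str,
    alpha: float = 0.05,
    min_studies: int = 2,
) -> list[PooledOR]:
    """Features whose BH-adjusted pooled p is below ``alpha``."""
    return [
        pr
        for pr in pool_features(collection, comparison, alpha, min_studies)
        if pr.significant
    ]


def pooled_or_frame(pooled: list[PooledOR]):
    """Long-format summary DataFrame (one row per pooled feature)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": [pr.feature_id for pr in pooled],
            "k": [pr.k for pr in pooled],
            "or": [pr.pooled_or for pr in pooled],
            "ci_lo": [pr.ci95[0] for pr in pooled],
            "ci_hi": [pr.ci95[1] for pr in pooled],
            "tau2": [pr.tau2 for pr in pooled],
            "p": [pr.p for pr in pooled],
            "p_bh": [pr.p_bh for pr in pooled],
            "significant": [pr.significant for pr in pooled],
        }
    )


def per_study_or_frame(pooled: list[PooledOR]):
    """Companion long-format frame with one row per (feature, study)."""
    import pandas as pd

    rows = []
    for pr in pooled:
        for study_id, r in pr.per_study.items():
            rows.append(
                {
                    "feature": pr.feature_id,
                    "study": study_id,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "or": r.odds_ratio,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "p_chisq": r.p_chisq,
                    "haldane": r.corrected,
                }
            )
    return pd.DataFrame(rows)
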