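"""Alpha diversity metrics, normalization, and disease-severity tests.

Per-sample richness, Shannon diversity (nats) and Pielou evenness are
computed on full counts (no rarefaction by default; an optional seeded
common-depth subsample is available). For study-adjusted severity tests
the metric is power transformed (Tukey ladder) and Z-normalized within
each study, then fit with a linear mixed model: metric ~ severity
(ordinal 0/1/2) + region, random intercept per study, plus a subject
variance component for tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crcmeta.io import MetaCollection, StudyTable, ValidationError
from crcmeta.meta_odds import ORResult, TwoByTwo, feature_table, odds_ratio

logger = logging.getLogger("crcmeta")

METRICS = ("richness", "shannon", "evenness")
SEVERITY = {"control": 0, "adenoma": 1, "carcinoma": 2}


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    shannon: float
    evenness: float


@dataclass(frozen=True)
class SeverityTestResult:
    metric: str
    coefficient: float
    p: float
    model: str


def alpha_metrics(counts: np.ndarray) -> DiversityResult:
    """Richness S, Shannon H (nats), Pielou evenness J = H/ln S.

    J is defined as 0 for a single-taxon sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("alpha_metrics takes a single sample's count vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    nz = counts[counts > 0]
    s = int(nz.size)
    p = nz / total
    h = float(-np.sum(p * np.log(p)))
    j = float(h / np.log(s)) if s >= 2 else 0.0
    return DiversityResult(richness=s, shannon=h, evenness=j)


def subsample_counts(
    counts: np.ndarray, depth: int, seed: int
) -> np.ndarray:
    """Seeded without-replacement subsample of one sample to a common depth."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below subsample depth {depth}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    picked = rng.choice(pool, size=depth, replace=False)
    return np.bincount(picked, minlength=counts.size)


def diversity_frame(
    study: StudyTable, subsample_depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample metrics table with metadata columns attached."""
    rows = []
    for i in range(study.n_samples):
        counts = study.counts[i]
        if subsample_depth is not None:
            counts = subsample_counts(counts, subsample_depth, seed + i)
        r = alpha_metrics(counts)
        row = {
            "sample_id": study.sample_ids[i],
            "study": study.study_id,
            "richness": r.richness,
            "shannon": r.shannon,
            "evenness": r.evenness,
        }
        if study.meta is not None:
            m = study.meta[i]
            row.update(
                diagnosis=m.diagnosis,
                site=m.site,
                subject_id=m.subject_id,
                region=m.region,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

#: Tukey ladder-of-powers search grid.
TUKEY_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.05), 2)


def _tukey_apply(x: np.ndarray, lam: float) -> np.ndarray:
    if lam > 0:
        return x**lam
    if lam == 0:
        return np.log(x)
    return -(x**lam)


def tukey_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Tukey ladder-of-powers transform maximizing Shapiro-Wilk W.

    Values are shifted to be strictly positive first when needed (the
    negative and log branches require positive input); the shift amount is
    data-derived and deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to choose a transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: no transform defined")
    if x.min() <= 0:
        x = x - x.min() + 1e-6 * np.ptp(x)
    best_lam, best_w = 1.0, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in TUKEY_GRID:
            t = _tukey_apply(x, float(lam))
            if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
                continue
            try:
                w = stats.shapiro(t).statistic
            except ValueError:
                continue
            if np.isfinite(w) and w > best_w:
                best_w, best_lam = float(w), float(lam)
    return _tukey_apply(x, best_lam), best_lam


def zscore(values: np.ndarray) -> np.ndarray:
    """Center and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 distinct values to Z-score")
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# Severity mixed model
# ---------------------------------------------------------------------------

def severity_test(
    collection: MetaCollection, metric: str, site: str
) -> SeverityTestResult:
    """Mixed-model test of metric ~ severity with a study random intercept.

    The metric is Tukey-transformed and Z-normalized within each study
    first. Region enters as a fixed effect when it varies; for tissue a
    subject variance component absorbs repeat sampling.
    """
    import statsmodels.formula.api as smf

    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(collection.studies) < 2:
        raise ValueError(
            "severity_test needs >=2 studies; use per-study tests for one study"
        )
    frames = []
    for study in collection.studies:
        df = diversity_frame(study)
        vals = df[metric].to_numpy(dtype=float)
        try:
            transformed, _ = tukey_transform(vals)
            df["value"] = zscore(transformed)
        except ValueError as exc:
            raise ValidationError(
                f"study {study.study_id}: cannot normalize {metric}: {exc}"
            ) from exc
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    data["severity"] = data["diagnosis"].map(SEVERITY)
    if data["severity"].nunique() < 2:
        raise ValidationError("no severity variance in collection")

    formula = "value ~ severity"
    if data["region"].nunique() > 1:
        formula += " + C(region)"
    vc = {"subject": "0 + C(subject_id)"} if site == "tissue" else None
    desc = f"{formula}, random intercept: study"
    if vc:
        desc += ", vc: subject"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data["study"], vc_formula=vc
        )
        fit = model.fit(reml=True, method="lbfgs")
    coef = float(fit.params["severity"])
    p = float(fit.pvalues["severity"])
    return SeverityTestResult(metric=metric, coefficient=coef, p=p, model=desc)


# ---------------------------------------------------------------------------
# Diversity odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityOR:
    study_id: str
    metric: str
    comparison: str
    table: TwoByTwo | None
    result: ORResult | None  # None when the 2x2 is degenerate

    @property
    def excluded(self) -> bool:
        return self.result is None


def diversity_or(
    study: StudyTable,
    metric: str,
    comparison: str,
    direction: str = "low",
    subsample_depth: int | None = None,
    seed: int = 0,
) -> DiversityOR:
    """Median-split odds ratio for one alpha metric in one study.

    ``direction='low'`` (default) marks samples strictly *below* the
    median of the two compared groups as exposed, so OR > 1 reads "low
    diversity is associated with disease"; ``direction='high'`` is the
    literal above-median reading and inverts the OR.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    df = diversity_frame(study, subsample_depth=subsample_depth, seed=seed)
    mask = df["diagnosis"].isin(["control", comparison])
    df = df[mask]
    is_case = (df["diagnosis"] == comparison).to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValidationError(
            f"study {study.study_id}: empty group for comparison {comparison}"
        )
    vals = df[metric].to_numpy(dtype=float)
    med = np.median(vals)
    exposed = vals < med if direction == "low" else vals > med
    table = feature_table(exposed, is_case)
    result = odds_ratio(table)
    if result is None:
        logger.info(
            "study %s: degenerate diversity 2x2 for %s/%s; excluded",
            study.study_id,
            metric,
            comparison,
        )
    return DiversityOR(
        study_id=study.study_id,
        metric=metric,
        comparison=comparison,
        table=table,
        result=result,
    )


def diversity_or_frame(
    collection: MetaCollection, comparison: str, direction: str = "low"
) -> pd.DataFrame:
    """Per-study diversity OR table across all metrics."""
    rows = []
    for study in collection.studies:
        d = study.diagnoses()
        if (d == comparison).sum() == 0 or (d == "control").sum() == 0:
            continue
        for metric in METRICS:
            dor = diversity_or(study, metric, comparison, direction=direction)
            row = {
                "study": study.study_id,
                "metric": metric,
                "comparison": comparison,
                "a": dor.table.a,
                "b": dor.table.b,
                "c": dor.table.c,
                "d": dor.table.d,
            }
            if dor.result is not None:
                row.update(
                    {
                        "or": dor.result.odds_ratio,
                        "ci_lo": dor.result.ci95[0],
                        "ci_hi": dor.result.ci95[1],
                        "p": dor.result.p_chisq,
                        "excluded": False,
                    }
                )
            else:
                row.update(
                    {
                        "or": np.nan,
                        "ci_lo": np.nan,
                        "ci_hi": np.nan,
                        "p": np.nan,
                        "excluded": True,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def pooled_diversity_or(
    collection: MetaCollection, metric: str, comparison: str, direction: str = "low"
):
    """Random-effects pooled diversity OR across studies (may be None)."""
    from crcmeta.meta_odds import pool_dl

    results = {}
    for study in collection.studies:
        d = study.diagnoses()
        if (d == comparison).sum() == 0 or (d == "control").sum() == 0:
            continue
        dor = diversity_or(study, metric, comparison, direction=direction)
        if dor.result is not None:
            results[study.study_id] = dor.result
    pooled = pool_dl(results)
    if pooled is not None:
        pooled.feature_id = f"{metric}:{comparison}"
    return pooled
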