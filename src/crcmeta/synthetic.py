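"""Synthetic multi-study case-control community generator.

Generates per-study count tables with the statistical structure the
downstream analysis assumes: strong study-level composition effects, a
small set of case-enriched taxa with patchy (zero-inflated) presence,
and protective taxa at reduced abundance in cases. Ground truth is
returned alongside so recovery can be tested.

Generative model per sample:

1. sequencing depth ~ NegativeBinomial(depth_mean, depth_dispersion)
2. base proportions ~ Dirichlet(base_concentration * rho), where rho is a
   fixed (seed-derived) community profile shared by all studies
3. multiply by exp(study effect) per taxon (study effects ~ N(0, sd))
4. every enriched taxon is independently zeroed with probability pi in
   all samples (presence is patchy regardless of diagnosis); when present
   in a case sample its abundance is multiplied by exp(log fold change)
5. protective taxa are multiplied by exp(negative log fold change) in
   case samples (no patchiness)
6. adenoma samples get effects scaled by adenoma_attenuation
7. renormalize, draw counts ~ Multinomial(depth, proportions)

Deterministic under (seed, study_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crcmeta.io import MetaCollection, SampleMeta, StudyTable, harmonize

# Independent RNG streams, keyed off (seed, stream[, study index]).
_STREAM_BASE = 101
_STREAM_STUDY_EFFECT = 202
_STREAM_SAMPLES = 303


@dataclass(frozen=True)
class EnrichedTaxon:
    """A case-enriched taxon: abundance fold change applies only when present."""

    index: int
    log_fold_change: float
    patchiness: float = 0.0  # P(absent) in any given sample

    def __post_init__(self) -> None:
        if not 0.0 <= self.patchiness < 1.0:
            raise ValueError("patchiness must be in [0, 1)")
        if not np.isfinite(self.log_fold_change):
            raise ValueError("log fold change must be finite")


@dataclass(frozen=True)
class ProtectiveTaxon:
    """A taxon at reduced abundance in cases (negative log fold change)."""

    index: int
    log_fold_change: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_fold_change):
            raise ValueError("log fold change must be finite")
        if self.log_fold_change >= 0:
            raise ValueError("protective log fold change must be negative")


@dataclass
class SyntheticConfig:
    n_studies: int
    group_sizes: list[tuple[int, int, int]]  # (control, adenoma, carcinoma)
    n_taxa: int
    seed: int = 0
    depth_mean: float = 10_000.0
    depth_dispersion: float = 5.0
    base_concentration: float = 200.0
    study_effect_sd: float = 1.0
    enriched_taxa: list[EnrichedTaxon] = field(default_factory=list)
    protective_taxa: list[ProtectiveTaxon] = field(default_factory=list)
    adenoma_attenuation: float = 0.25
    site: str = "feces"
    study_ids: list[str] | None = None
    regions: list[str] | None = None
    matched: list[bool] | None = None  # matched case/control subjects (tissue)

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_taxa < 1:
            raise ValueError("need at least one study and one taxon")
        if len(self.group_sizes) != self.n_studies:
            raise ValueError("group_sizes must have one triple per study")
        for gs in self.group_sizes:
            if len(gs) != 3 or any(g < 0 for g in gs):
                raise ValueError("group sizes must be non-negative triples")
            if sum(gs) == 0:
                raise ValueError("every study needs at least one sample")
        if not 0.0 <= self.adenoma_attenuation <= 1.0:
            raise ValueError("adenoma_attenuation must be in [0, 1]")
        enriched = {t.index for t in self.enriched_taxa}
        protective = {t.index for t in self.protective_taxa}
        if enriched & protective:
            raise ValueError("enriched and protective taxa must be disjoint")
        for i in enriched | protective:
            if not 0 <= i < self.n_taxa:
                raise ValueError(f"effect taxon index {i} out of range")
        if self.study_ids is None:
            self.study_ids = [f"study{i + 1}" for i in range(self.n_studies)]
        if self.regions is None:
            self.regions = ["V4"] * self.n_studies
        if self.matched is None:
            self.matched = [False] * self.n_studies
        for name, lst in (("study_ids", self.study_ids), ("regions", self.regions),
                          ("matched", self.matched)):
            if len(lst) != self.n_studies:
                raise ValueError(f"{name} must have one entry per study")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated collection."""

    feature_ids: list[str]
    labels: list[str]  # enriched | protective | null, one per taxon
    log_fold_changes: np.ndarray
    patchiness: np.ndarray
    study_effects: dict[str, np.ndarray]  # study_id -> per-taxon log effects

    def true_positive_set(self) -> set[str]:
        return {
            f
            for f, lab in zip(self.feature_ids, self.labels)
            if lab != "null"
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "label": self.labels,
                "log_fold_change": self.log_fold_changes,
                "patchiness": self.patchiness,
            }
        )


def _feature_ids(n_taxa: int) -> list[str]:
    width = max(3, len(str(n_taxa)))
    return [f"Taxon{str(i + 1).zfill(width)}" for i in range(n_taxa)]


def _base_profile(config: SyntheticConfig) -> np.ndarray:
    """Fixed community profile, sorted most-abundant-first so that effect
    taxon indices chosen near the front are reliably detectable."""
    rng = np.random.default_rng([config.seed, _STREAM_BASE])
    rho = np.exp(rng.normal(0.0, 1.5, size=config.n_taxa))
    rho = np.sort(rho)[::-1]
    return rho / rho.sum()


def _study_effects(config: SyntheticConfig, study_index: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, _STREAM_STUDY_EFFECT, study_index])
    return rng.normal(0.0, config.study_effect_sd, size=config.n_taxa)


def generate_study(config: SyntheticConfig, study_index: int) -> StudyTable:
    """Generate one study's count table; deterministic under (seed, index)."""
    if not 0 <= study_index < config.n_studies:
        raise ValueError("study_index out of range")
    n_control, n_adenoma, n_carcinoma = config.group_sizes[study_index]
    diagnoses = (
        ["control"] * n_control + ["adenoma"] * n_adenoma + ["carcinoma"] * n_carcinoma
    )
    n = len(diagnoses)
    rng = np.random.default_rng([config.seed, _STREAM_SAMPLES, study_index])

    rho = _base_profile(config)
    alpha = config.base_concentration * rho
    delta = np.exp(_study_effects(config, study_index))

    p_disp = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depths = rng.negative_binomial(config.depth_dispersion, p_disp, size=n)
    depths = np.maximum(depths, 100)  # keep every sample's total positive

    counts = np.zeros((n, config.n_taxa), dtype=np.int64)
    for i, diag in enumerate(diagnoses):
        w = rng.dirichlet(alpha) * delta
        scale = {"control": 0.0, "adenoma": config.adenoma_attenuation,
                 "carcinoma": 1.0}[diag]
        for t in config.enriched_taxa:
            if rng.random() < t.patchiness:
                w[t.index] = 0.0
            elif scale > 0.0:
                w[t.index] *= np.exp(t.log_fold_change * scale)
        if scale > 0.0:
            for t in config.protective_taxa:
                w[t.index] *= np.exp(t.log_fold_change * scale)
        total = w.sum()
        if total == 0:
            raise RuntimeError("all-zero expected proportions; check config")
        counts[i] = rng.multinomial(depths[i], w / total)

    study_id = config.study_ids[study_index]
    sample_ids = [f"{study_id}_s{i:04d}" for i in range(n)]
    subject_ids = [f"{study_id}_u{i:04d}" for i in range(n)]
    matched = bool(config.matched[study_index])
    if matched:
        # pair the i-th case with the i-th control subject where possible
        case_idx = [i for i, d in enumerate(diagnoses) if d != "control"]
        ctrl_idx = [i for i, d in enumerate(diagnoses) if d == "control"]
        for k, ci in enumerate(case_idx):
            if k < len(ctrl_idx):
                subject_ids[ci] = subject_ids[ctrl_idx[k]]
    paired = {s for s in subject_ids if subject_ids.count(s) > 1}
    meta = [
        SampleMeta(
            sample_id=sid,
            study_id=study_id,
            diagnosis=diag,
            site=config.site,
            subject_id=subj,
            matched=matched and subj in paired,
            region=config.regions[study_index],
        )
        for sid, subj, diag in zip(sample_ids, subject_ids, diagnoses)
    ]
    return StudyTable(
        study_id=study_id,
        feature_ids=_feature_ids(config.n_taxa),
        feature_level="taxon",
        counts=counts,
        sample_ids=sample_ids,
        meta=meta,
    )


def generate_collection(
    config: SyntheticConfig,
) -> tuple[MetaCollection, SyntheticTruth]:
    """Generate all studies plus the ground-truth record."""
    studies = [generate_study(config, i) for i in range(config.n_studies)]
    collection = harmonize(studies)

    labels = ["null"] * config.n_taxa
    lfc = np.zeros(config.n_taxa)
    pi = np.zeros(config.n_taxa)
    for t in config.enriched_taxa:
        labels[t.index] = "enriched"
        lfc[t.index] = t.log_fold_change
        pi[t.index] = t.patchiness
    for t in config.protective_taxa:
        labels[t.index] = "protective"
        lfc[t.index] = t.log_fold_change
    truth = SyntheticTruth(
        feature_ids=_feature_ids(config.n_taxa),
        labels=labels,
        log_fold_changes=lfc,
        patchiness=pi,
        study_effects={
            config.study_ids[i]: _study_effects(config, i)
            for i in range(config.n_studies)
        },
    )
    return collection, truth


# ---------------------------------------------------------------------------
# Default multi-cohort designs
# ---------------------------------------------------------------------------

# (study, 16S region, n control, n adenoma, n carcinoma)
FECAL_DESIGN: list[tuple[str, str, int, int, int]] = [
    ("Ahn", "V3-V4", 148, 0, 62),
    ("Baxter", "V4", 172, 198, 120),
    ("Brim", "V1-V3", 6, 6, 0),
    ("Flemer", "V3-V4", 37, 0, 43),
    ("Hale", "V3-V5", 473, 214, 17),
    ("Wang", "V3", 56, 0, 46),
    ("Weir", "V4", 4, 0, 7),
    ("Zeller", "V4", 50, 37, 41),
]

TISSUE_DESIGN: list[tuple[str, str, int, int, int]] = [
    ("Burns", "V5-V6", 18, 0, 16),
    ("Chen", "V1-V3", 9, 0, 9),
    ("Dejea", "V3-V5", 31, 0, 32),
    ("Flemer", "V3-V4", 103, 37, 94),
    ("Geng", "V1-V2", 16, 0, 16),
    ("Lu", "V3-V4", 20, 20, 0),
    ("Sanapareddy", "V1-V2", 38, 0, 33),
]

# Default disease signal: 4 patchy enriched taxa, 2 protective taxa.
# Indices sit at mid-abundance ranks (~0.5-1% relative abundance): abundant
# enough for the median split to be informative, rare enough that the
# compositional spillover onto null taxa stays below detection.
DEFAULT_ENRICHED = [
    EnrichedTaxon(index=24, log_fold_change=1.0, patchiness=0.3),
    EnrichedTaxon(index=25, log_fold_change=1.0, patchiness=0.3),
    EnrichedTaxon(index=26, log_fold_change=1.0, patchiness=0.3),
    EnrichedTaxon(index=27, log_fold_change=1.0, patchiness=0.3),
]
DEFAULT_PROTECTIVE = [
    ProtectiveTaxon(index=31, log_fold_change=-0.5),
    ProtectiveTaxon(index=32, log_fold_change=-0.5),
]


def _design_config(
    design: list[tuple[str, str, int, int, int]],
    site: str,
    seed: int,
    n_taxa: int,
    scale: float,
    **overrides: object,
) -> SyntheticConfig:
    sizes = []
    for _, _, c, a, k in design:
        if scale == 1.0:
            sizes.append((c, a, k))
        else:
            scaled = tuple(int(round(g * scale)) if g else 0 for g in (c, a, k))
            if sum(scaled) == 0:
                scaled = (max(scaled[0], 2), scaled[1], scaled[2])
            # keep non-empty groups usable for CV after scaling
            scaled = tuple(
                (max(g, 4) if orig else 0)
                for g, orig in zip(scaled, (c, a, k))
            )
            sizes.append(scaled)
    kwargs: dict = dict(
        n_studies=len(design),
        group_sizes=sizes,
        n_taxa=n_taxa,
        seed=seed,
        site=site,
        study_ids=[d[0] for d in design],
        regions=[d[1] for d in design],
        enriched_taxa=list(DEFAULT_ENRICHED),
        protective_taxa=list(DEFAULT_PROTECTIVE),
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def default_fecal_config(
    seed: int = 0, n_taxa: int = 200, scale: float = 1.0, **overrides: object
) -> SyntheticConfig:
    """8 fecal cohorts with the default multi-cohort group sizes."""
    return _design_config(FECAL_DESIGN, "feces", seed, n_taxa, scale, **overrides)


def default_tissue_config(
    seed: int = 0, n_taxa: int = 200, scale: float = 1.0, **overrides: object
) -> SyntheticConfig:
    """7 tissue cohorts with the default multi-cohort group sizes."""
    return _design_config(TISSUE_DESIGN, "tissue", seed, n_taxa, scale, **overrides)
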