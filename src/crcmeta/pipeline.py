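"""Configuration-driven orchestration of the full meta-analysis.

Stage order mirrors the analysis narrative: simulate/load -> alpha
diversity (+ diversity ORs) -> per-study PERMANOVA -> pooled taxon ORs ->
single-feature AUCs -> per-study CV AUCs per regime -> MDA Z ranking ->
cross-study transfer. Every output is a TSV with a provenance header; a
JSON manifest records versions, seeds, and emitted files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from crcmeta import __version__
from crcmeta.alpha import METRICS, diversity_frame, diversity_or_frame, severity_test
from crcmeta.beta import study_permanova
from crcmeta.classify import (
    cv_auc,
    mda_zscores,
    regime_features,
    single_taxon_auc,
    transfer_evaluate,
)
from crcmeta.io import (
    MetaCollection,
    attach_metadata,
    harmonize,
    read_feature_table,
    write_feature_table,
    write_metadata,
    write_result_table,
)
from crcmeta.meta_odds import per_study_or_frame, pool_features, pooled_or_frame
from crcmeta.synthetic import (
    SyntheticConfig,
    default_fecal_config,
    default_tissue_config,
    generate_collection,
)

logger = logging.getLogger("crcmeta")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | load
    site: str = "feces"
    out_dir: str = "crcmeta_out"
    comparisons: list[str] = field(default_factory=lambda: ["adenoma", "carcinoma"])
    alpha: float = 0.05
    folds: int = 10
    repeats: int = 1
    n_estimators: int = 500
    seed: int = 1
    n_perm: int = 999
    # load mode
    table_paths: list[str] = field(default_factory=list)
    metadata_path: str | None = None
    dialect: str = "tsv"
    min_total: int = 100
    # simulate mode
    synthetic: SyntheticConfig | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            from crcmeta.synthetic import EnrichedTaxon, ProtectiveTaxon

            syn["enriched_taxa"] = [
                EnrichedTaxon(**t) for t in syn.get("enriched_taxa", [])
            ]
            syn["protective_taxa"] = [
                ProtectiveTaxon(**t) for t in syn.get("protective_taxa", [])
            ]
            syn["group_sizes"] = [tuple(g) for g in syn["group_sizes"]]
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed from one global seed (counter scheme)."""
    stages = (
        "simulate",
        "diversity",
        "permanova",
        "meta_or",
        "single_auc",
        "classify",
        "transfer",
    )
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    return seed * 1000 + stages.index(stage)


def _load_collection(config: PipelineConfig) -> MetaCollection:
    if config.mode == "simulate":
        syn = config.synthetic
        if syn is None:
            maker = (
                default_fecal_config if config.site == "feces" else default_tissue_config
            )
            syn = maker(seed=config.seed)
        collection, truth = generate_collection(syn)
        out = Path(config.out_dir)
        for s in collection.studies:
            write_feature_table(s, out / f"{s.study_id}.tsv")
        write_metadata(collection.studies, out / "metadata.tsv")
        write_result_table(truth.to_frame(), out / "truth.tsv", seed=syn.seed)
        return collection
    if not config.table_paths or config.metadata_path is None:
        raise ValueError("load mode requires table_paths and metadata_path")
    tables = []
    for p in config.table_paths:
        t = read_feature_table(p, dialect=config.dialect, min_total=config.min_total)
        tables.append(attach_metadata(t, config.metadata_path))
    return harmonize(tables)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with the stage name; outputs written before
    the failure are retained next to a FAILED marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "site": config.site,
        "mode": config.mode,
        "outputs": [],
        "stages": {},
    }

    def emit(df: pd.DataFrame, name: str, **extra) -> None:
        write_result_table(df, out / name, seed=config.seed, **extra)
        manifest["outputs"].append(name)

    stage = "setup"
    try:
        t0 = time.time()
        stage = "simulate" if config.mode == "simulate" else "load"
        collection = _load_collection(config)
        manifest["studies"] = collection.study_ids
        manifest["n_samples"] = collection.n_samples
        manifest["stages"][stage] = round(time.time() - t0, 2)
        logger.info("stage %s done (%d studies)", stage, len(collection.studies))

        # -- diversity ----------------------------------------------------
        stage = "diversity"
        t0 = time.time()
        div = pd.concat(
            [diversity_frame(s) for s in collection.studies], ignore_index=True
        )
        emit(div, "diversity.tsv")
        sev_rows = []
        for metric in METRICS:
            try:
                r = severity_test(collection, metric, config.site)
                sev_rows.append(
                    {"metric": metric, "coefficient": r.coefficient, "p": r.p,
                     "model": r.model}
                )
            except Exception as exc:  # per-metric failure is not fatal
                logger.warning("severity test failed for %s: %s", metric, exc)
        emit(pd.DataFrame(sev_rows), "severity_tests.tsv")
        frames = [
            diversity_or_frame(collection, comparison)
            for comparison in config.comparisons
        ]
        emit(pd.concat(frames, ignore_index=True), "diversity_or.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

        # -- permanova ----------------------------------------------------
        stage = "permanova"
        t0 = time.time()
        rows = []
        for comparison in config.comparisons:
            for s in collection.studies:
                d = s.diagnoses()
                if (d == comparison).sum() < 3 or (d == "control").sum() < 3:
                    logger.info(
                        "study %s skipped for %s PERMANOVA", s.study_id, comparison
                    )
                    continue
                r = study_permanova(
                    s, comparison, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "permanova"),
                )
                rows.append(
                    {
                        "study": s.study_id,
                        "comparison": comparison,
                        "pseudo_f": r.pseudo_f,
                        "p": r.p,
                        "n_permutations": r.n_permutations,
                    }
                )
        emit(pd.DataFrame(rows), "permanova.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

        # -- pooled ORs ---------------------------------------------------
        stage = "meta_or"
        t0 = time.time()
        sig_by_comparison: dict[str, list[str]] = {}
        pooled_frames, per_study_frames = [], []
        for comparison in config.comparisons:
            pooled = pool_features(collection, comparison, alpha=config.alpha)
            pf = pooled_or_frame(pooled)
            pf.insert(0, "comparison", comparison)
            pooled_frames.append(pf)
            psf = per_study_or_frame(pooled)
            psf.insert(0, "comparison", comparison)
            per_study_frames.append(psf)
            sig_by_comparison[comparison] = [
                pr.feature_id for pr in pooled if pr.significant
            ]
        emit(pd.concat(pooled_frames, ignore_index=True), "pooled_or.tsv")
        emit(pd.concat(per_study_frames, ignore_index=True), "per_study_or.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

        # -- single-feature AUCs -----------------------------------------
        stage = "single_auc"
        t0 = time.time()
        rows = []
        for comparison in config.comparisons:
            for f in sig_by_comparison[comparison]:
                for s in collection.studies:
                    d = s.diagnoses()
                    if (d == comparison).sum() == 0 or (d == "control").sum() == 0:
                        continue
                    rows.append(
                        {
                            "comparison": comparison,
                            "feature": f,
                            "study": s.study_id,
                            "auc": single_taxon_auc(s, f, comparison),
                        }
                    )
        emit(pd.DataFrame(rows), "single_taxon_auc.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

        # -- per-study CV per regime -------------------------------------
        stage = "classify"
        t0 = time.time()
        rows = []
        cv_by_key: dict[tuple[str, str], list] = {}
        for comparison in config.comparisons:
            for regime in ("sig_or_taxa", "all_taxa"):
                if regime == "sig_or_taxa" and not sig_by_comparison[comparison]:
                    logger.info(
                        "no significant taxa for %s; sig_or_taxa models skipped",
                        comparison,
                    )
                    continue
                feats = (
                    sig_by_comparison[comparison]
                    if regime == "sig_or_taxa"
                    else list(collection.feature_union)
                )
                results = []
                for s in collection.studies:
                    d = s.diagnoses()
                    if (d == comparison).sum() < 2 or (d == "control").sum() < 2:
                        continue
                    r = cv_auc(
                        s,
                        feats,
                        comparison,
                        regime=regime,
                        k=config.folds,
                        repeats=config.repeats,
                        seed=stage_seed(config.seed, "classify"),
                        n_estimators=config.n_estimators,
                    )
                    results.append(r)
                    rows.append(
                        {
                            "comparison": comparison,
                            "regime": regime,
                            "study": s.study_id,
                            "k": r.k,
                            "auc": r.auc,
                        }
                    )
                cv_by_key[(comparison, regime)] = results
        emit(pd.DataFrame(rows), "cv_auc.tsv")
        rank_frames = []
        for (comparison, regime), results in cv_by_key.items():
            if not results:
                continue
            try:
                z = mda_zscores(results).reset_index()
            except ValueError as exc:
                logger.warning(
                    "MDA ranking skipped (%s/%s): %s", comparison, regime, exc
                )
                continue
            z.insert(0, "regime", regime)
            z.insert(0, "comparison", comparison)
            rank_frames.append(z)
        if rank_frames:
            emit(pd.concat(rank_frames, ignore_index=True), "mda_ranking.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

        # -- transfer -----------------------------------------------------
        stage = "transfer"
        t0 = time.time()
        tm_frames = []
        for comparison in config.comparisons:
            for regime in ("sig_or_taxa", "all_taxa"):
                try:
                    tm = transfer_evaluate(
                        collection,
                        regime,
                        comparison,
                        seed=stage_seed(config.seed, "transfer"),
                        alpha=config.alpha,
                        n_estimators=config.n_estimators,
                        cv_k=config.folds,
                    )
                except ValueError as exc:
                    logger.warning("transfer skipped (%s/%s): %s", comparison, regime, exc)
                    continue
                df = tm.to_frame().reset_index()
                df.insert(0, "regime", regime)
                df.insert(0, "comparison", comparison)
                tm_frames.append(df)
        if tm_frames:
            emit(pd.concat(tm_frames, ignore_index=True), "transfer.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 2)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
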