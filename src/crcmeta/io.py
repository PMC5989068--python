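"""Data model and I/O for multi-study count tables.

Orientation convention: samples in rows, features in columns, everywhere.
All tabular output is TSV with a commented header line recording the
package version and, when relevant, the seed that produced the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crcmeta")

DIAGNOSES = ("control", "adenoma", "carcinoma")
SITES = ("feces", "tissue")
FEATURE_LEVELS = ("taxon", "otu")

METADATA_COLUMNS = ("sample_id", "diagnosis", "site", "subject_id", "matched", "region")


class ParseError(ValueError):
    """Raised when a file cannot be parsed into a table."""


class ValidationError(ValueError):
    """Raised when parsed data violates a model invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations.

    ``matched`` marks tissue samples where tumor and unaffected tissue come
    from the same subject; in that case ``subject_id`` repeats within the
    study.
    """

    sample_id: str
    study_id: str
    diagnosis: str
    site: str
    subject_id: str
    matched: bool = False
    region: str = ""

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"unknown diagnosis {self.diagnosis!r}; allowed: {DIAGNOSES}"
            )
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}; allowed: {SITES}")


@dataclass
class StudyTable:
    """One cohort's count matrix plus sample metadata.

    ``meta`` is ``None`` until :func:`attach_metadata` has run; every
    operation that needs diagnoses checks for that.
    """

    study_id: str
    feature_ids: list[str]
    feature_level: str
    counts: np.ndarray  # samples x features, non-negative integers
    sample_ids: list[str]
    meta: list[SampleMeta] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.feature_level not in FEATURE_LEVELS:
            raise ValidationError(f"feature_level must be one of {FEATURE_LEVELS}")
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-d samples x features matrix")
        n, p = self.counts.shape
        if n != len(self.sample_ids):
            raise ValidationError("row count does not match number of sample ids")
        if p != len(self.feature_ids):
            raise ValidationError("column count does not match number of feature ids")
        if len(set(self.feature_ids)) != p:
            raise ValidationError("feature_ids are not unique")
        if len(set(self.sample_ids)) != n:
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]}, "
                    f"feature {self.feature_ids[bad[1]]}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]}, "
                f"feature {self.feature_ids[bad[1]]}"
            )
        totals = self.counts.sum(axis=1)
        if n and totals.min() == 0:
            zero = [self.sample_ids[i] for i in np.flatnonzero(totals == 0)]
            raise ValidationError(f"samples with zero total count: {zero}")
        if self.meta is not None:
            if len(self.meta) != n:
                raise ValidationError("metadata row count does not match samples")
            for sid, m in zip(self.sample_ids, self.meta):
                if m.sample_id != sid:
                    raise ValidationError("metadata out of order with samples")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def diagnoses(self) -> np.ndarray:
        if self.meta is None:
            raise ValidationError(f"study {self.study_id}: metadata not attached")
        return np.array([m.diagnosis for m in self.meta])

    def subset(self, mask: np.ndarray) -> "StudyTable":
        """Row-subset by boolean mask, keeping metadata aligned."""
        idx = np.flatnonzero(np.asarray(mask))
        meta = [self.meta[i] for i in idx] if self.meta is not None else None
        return StudyTable(
            study_id=self.study_id,
            feature_ids=list(self.feature_ids),
            feature_level=self.feature_level,
            counts=self.counts[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            meta=meta,
        )

    def comparison_subset(self, comparison: str) -> "StudyTable":
        """Keep only controls and the requested case group."""
        if comparison not in ("adenoma", "carcinoma"):
            raise ValidationError("comparison must be 'adenoma' or 'carcinoma'")
        d = self.diagnoses()
        return self.subset((d == "control") | (d == comparison))


@dataclass
class MetaCollection:
    """A harmonized set of StudyTables sharing one feature namespace."""

    studies: list[StudyTable]
    feature_level: str
    feature_union: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.studies:
            if s.feature_level != self.feature_level:
                raise ValidationError("mixed feature levels in collection")
        seen = set()
        for s in self.studies:
            if s.study_id in seen:
                raise ValidationError(f"duplicate study id {s.study_id}")
            seen.add(s.study_id)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def get(self, study_id: str) -> StudyTable:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.studies)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path,
    dialect: str = "tsv",
    study_id: str | None = None,
    feature_level: str = "taxon",
    min_total: int = 1,
) -> StudyTable:
    """Read a samples x features count table.

    ``dialect='tsv'``: header row of feature ids, first column sample ids.
    ``dialect='mothur_shared'``: mothur shared-file layout with columns
    ``label, Group, numOtus, Otu...``.

    Samples with total count below ``min_total`` are rejected with an
    error; the CLI exposes this as ``--min-total`` (default 100) so that
    low-coverage exclusions are always explicit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if study_id is None:
        study_id = path.stem
    if dialect == "tsv":
        sample_ids, feature_ids, counts = _read_tsv_counts(path)
    elif dialect == "mothur_shared":
        sample_ids, feature_ids, counts = _read_mothur_shared(path)
        feature_level = "otu"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    table = StudyTable(
        study_id=study_id,
        feature_ids=feature_ids,
        feature_level=feature_level,
        counts=counts,
        sample_ids=sample_ids,
    )
    low = table.totals() < min_total
    if low.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(low)]
        raise ValidationError(
            f"{path.name}: {len(bad)} sample(s) below min total count "
            f"{min_total}: {bad[:10]}"
        )
    return table


def _read_tsv_counts(path: Path):
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path.name}: empty file") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path.name}: {exc}") from None
    if df.shape[1] == 0:
        raise ParseError(f"{path.name}: header has no feature columns (line 1)")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path.name}: non-numeric cell in column {col!r} at sample "
                f"{bad.index[0]!r}"
            )
    return (
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(),
    )


def _read_mothur_shared(path: Path):
    try:
        df = pd.read_csv(path, sep=r"\s+", header=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path.name}: empty file") from None
    expected = ["label", "Group", "numOtus"]
    if list(df.columns[:3]) != expected:
        raise ParseError(
            f"{path.name}: shared file must start with columns {expected}, "
            f"found {list(df.columns[:3])} (line 1)"
        )
    otu_cols = list(df.columns[3:])
    if not otu_cols:
        raise ParseError(f"{path.name}: no OTU columns (line 1)")
    declared = df["numOtus"].to_numpy()
    if not np.all(declared == len(otu_cols)):
        bad = int(np.flatnonzero(declared != len(otu_cols))[0])
        raise ValidationError(
            f"{path.name}: numOtus={declared[bad]} on data line {bad + 2} "
            f"but {len(otu_cols)} OTU columns present"
        )
    counts = df[otu_cols].to_numpy()
    return [str(g) for g in df["Group"]], [str(c) for c in otu_cols], counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata TSV with the six required columns (+ optional study_id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path.name}: empty metadata file") from None
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing metadata columns {missing}")
    for col, allowed in (("diagnosis", DIAGNOSES), ("site", SITES)):
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValidationError(
                f"{path.name}: unknown {col} token(s) {bad}; allowed: {list(allowed)}"
            )
    bad_bool = sorted(set(df["matched"].str.lower()) - {"true", "false"})
    if bad_bool:
        raise ValidationError(
            f"{path.name}: matched must be true/false, found {bad_bool}"
        )
    df["matched"] = df["matched"].str.lower() == "true"
    return df


def attach_metadata(table: StudyTable, meta_path: str | Path) -> StudyTable:
    """Join metadata rows onto a study table by ``sample_id``.

    Samples without a metadata row are dropped (count logged); metadata
    rows without a sample are ignored (count logged). Zero overlap is an
    error.
    """
    df = read_metadata(meta_path)
    if "study_id" in df.columns:
        df = df[df["study_id"].isin([table.study_id]) | df["study_id"].isna()]
    by_id = {r.sample_id: r for r in df.itertuples(index=False)}
    keep = [i for i, sid in enumerate(table.sample_ids) if sid in by_id]
    n_dropped = table.n_samples - len(keep)
    if not keep:
        raise ValidationError(
            f"study {table.study_id}: zero samples overlap with metadata"
        )
    if n_dropped:
        logger.info(
            "study %s: dropped %d sample(s) without metadata", table.study_id, n_dropped
        )
    n_unused = len(by_id) - len(keep)
    if n_unused:
        logger.info(
            "study %s: ignored %d metadata row(s) without samples",
            table.study_id,
            n_unused,
        )
    sub = table.subset(np.isin(np.arange(table.n_samples), keep))
    meta = []
    for sid in sub.sample_ids:
        r = by_id[sid]
        meta.append(
            SampleMeta(
                sample_id=sid,
                study_id=table.study_id,
                diagnosis=r.diagnosis,
                site=r.site,
                subject_id=str(r.subject_id),
                matched=bool(r.matched),
                region=str(r.region),
            )
        )
    _check_matched(meta, table.study_id)
    return replace(sub, meta=meta)


def _check_matched(meta: Sequence[SampleMeta], study_id: str) -> None:
    subj_counts: dict[str, int] = {}
    for m in meta:
        subj_counts[m.subject_id] = subj_counts.get(m.subject_id, 0) + 1
    for m in meta:
        if m.matched and subj_counts[m.subject_id] < 2:
            raise ValidationError(
                f"study {study_id}: sample {m.sample_id} is matched but subject "
                f"{m.subject_id} appears only once"
            )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_relative_abundance(table: StudyTable | np.ndarray) -> np.ndarray:
    """Row-normalize counts to proportions (each row sums to 1)."""
    counts = table.counts if isinstance(table, StudyTable) else np.asarray(table)
    totals = counts.sum(axis=1, dtype=float)
    if np.any(totals == 0):
        if isinstance(table, StudyTable):
            zero = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        else:
            zero = list(np.flatnonzero(totals == 0))
        raise ValidationError(f"zero-total sample(s): {zero}")
    return counts / totals[:, None]


def harmonize(studies: Iterable[StudyTable]) -> MetaCollection:
    """Reindex taxon-level studies onto the union of their feature names.

    Absent features get explicit zero columns; per-sample totals are
    unchanged. Matching is exact-string on classifier labels. OTU-level
    tables cannot be harmonized (namespaces are per-study by construction).
    """
    studies = list(studies)
    if not studies:
        raise ValidationError("no studies to harmonize")
    levels = {s.feature_level for s in studies}
    if levels != {"taxon"}:
        raise ValidationError(
            f"harmonize requires taxon-level tables; found levels {sorted(levels)}"
        )
    union: list[str] = []
    seen: set[str] = set()
    for s in studies:
        for f in s.feature_ids:
            if f not in seen:
                seen.add(f)
                union.append(f)
    out = []
    for s in studies:
        pos = {f: j for j, f in enumerate(s.feature_ids)}
        counts = np.zeros((s.n_samples, len(union)), dtype=s.counts.dtype)
        for j, f in enumerate(union):
            if f in pos:
                counts[:, j] = s.counts[:, pos[f]]
        out.append(replace(s, feature_ids=list(union), counts=counts))
    return MetaCollection(studies=out, feature_level="taxon", feature_union=union)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _header_comment(seed: int | None = None, **extra: object) -> str:
    from crcmeta import __version__

    parts = [f"crcmeta v{__version__}", "orientation=samples-in-rows"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in extra.items())
    return "# " + " ".join(parts) + "\n"


def write_feature_table(
    table: StudyTable, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write counts in a round-trippable dialect (tsv or mothur_shared)."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.DataFrame(
            table.counts, index=table.sample_ids, columns=table.feature_ids
        )
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif dialect == "mothur_shared":
        df = pd.DataFrame(
            table.counts, index=table.sample_ids, columns=table.feature_ids
        )
        df.insert(0, "label", "0.03")
        df.insert(1, "Group", table.sample_ids)
        df.insert(2, "numOtus", table.n_features)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_metadata(tables: Iterable[StudyTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        if t.meta is None:
            raise ValidationError(f"study {t.study_id}: metadata not attached")
        for m in t.meta:
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "study_id": m.study_id,
                    "diagnosis": m.diagnosis,
                    "site": m.site,
                    "subject_id": m.subject_id,
                    "matched": "true" if m.matched else "false",
                    "region": m.region,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_result_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, **extra: object
) -> None:
    """Write a result TSV with a commented provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed=seed, **extra))
        df.to_csv(fh, sep="\t", index=False)
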