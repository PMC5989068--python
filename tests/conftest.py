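import numpy as np
import pytest

from crcmeta.io import SampleMeta, StudyTable


def make_study(
    counts,
    study_id="s1",
    diagnoses=None,
    site="feces",
    feature_ids=None,
    region="V4",
    subject_ids=None,
    matched=None,
):
    counts = np.asarray(counts)
    n, p = counts.shape
    if feature_ids is None:
        feature_ids = [f"T{j}" for j in range(p)]
    if diagnoses is None:
        diagnoses = ["control"] * n
    sample_ids = [f"{study_id}_{i}" for i in range(n)]
    if subject_ids is None:
        subject_ids = [f"{study_id}_u{i}" for i in range(n)]
    if matched is None:
        matched = [False] * n
    meta = [
        SampleMeta(
            sample_id=sid,
            study_id=study_id,
            diagnosis=d,
            site=site,
            subject_id=u,
            matched=m,
            region=region,
        )
        for sid, d, u, m in zip(sample_ids, diagnoses, subject_ids, matched)
    ]
    return StudyTable(
        study_id=study_id,
        feature_ids=list(feature_ids),
        feature_level="taxon",
        counts=counts,
        sample_ids=sample_ids,
        meta=meta,
    )


@pytest.fixture
def two_group_study():
    """Small balanced case/control study with non-trivial counts."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 50, size=(20, 10))
    diagnoses = ["control"] * 10 + ["carcinoma"] * 10
    return make_study(counts, diagnoses=diagnoses)
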