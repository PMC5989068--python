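"""Bray-Curtis dissimilarity and one-way PERMANOVA.

The pseudo-F follows the one-way formulation on squared dissimilarities:
SS_total = (1/n) * sum_{i<j} d_ij^2, SS_within = sum over groups of
(1/n_g) * sum_{i<j in g} d_ij^2, F = ((SS_T - SS_W)/(g-1)) / (SS_W/(n-g)).
Significance comes from seeded label permutations; with matched samples
the permutations are restricted to swaps within subject strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from crcmeta.io import StudyTable, to_relative_abundance


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample ids do not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis entries must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    groups: tuple[str, str]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("inputs must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(
    study: StudyTable | np.ndarray, use_relative: bool = True
) -> DistanceMatrix:
    """Pairwise Bray-Curtis over samples (on relative abundances by default)."""
    if isinstance(study, StudyTable):
        data = to_relative_abundance(study) if use_relative else study.counts
        ids = list(study.sample_ids)
    else:
        data = np.asarray(study, dtype=float)
        ids = [str(i) for i in range(data.shape[0])]
    d = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(sample_ids=ids, values=d)


def _pseudo_f_terms(d2: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """SS_within for a batch of group-indicator rows.

    ``masks`` is (B, n) boolean for group 1; the complement is group 2.
    Returns the (B,) vector of within-group sums of squares.
    """
    n1 = masks.sum(axis=1).astype(float)
    n2 = masks.shape[1] - n1
    m = masks.astype(float)
    c = 1.0 - m
    within1 = np.einsum("bi,ij,bj->b", m, d2, m) / 2.0
    within2 = np.einsum("bi,ij,bj->b", c, d2, c) / 2.0
    return within1 / n1 + within2 / n2


def pseudo_f(dist: DistanceMatrix, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F for a two-group labeling."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("labels must form exactly two groups")
    n = dist.n
    if labels.size != n:
        raise ValueError("labels do not align with the matrix")
    d2 = dist.values**2
    ss_total = d2.sum() / (2.0 * n)
    mask = (labels == groups[0])[None, :]
    ss_within = float(_pseudo_f_terms(d2, mask)[0])
    df_between, df_within = 1, n - 2
    return float(((ss_total - ss_within) / df_between) / (ss_within / df_within))


def permanova(
    dist: DistanceMatrix,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    strata: np.ndarray | None = None,
) -> PermanovaResult:
    """Permutation test of the two-group pseudo-F.

    ``strata`` (e.g. subject ids for matched tissue) restricts shuffles to
    within-stratum label permutations. p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), so p is never 0 and has resolution 1/(n_perm + 1).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("labels must form exactly two groups")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    n = dist.n
    d2 = dist.values**2
    ss_total = d2.sum() / (2.0 * n)
    df_within = n - 2

    base = (labels == groups[0]).astype(bool)
    rng = np.random.default_rng(seed)
    perm_masks = np.empty((n_perm + 1, n), dtype=bool)
    perm_masks[0] = base
    if strata is None:
        for b in range(1, n_perm + 1):
            perm_masks[b] = base[rng.permutation(n)]
    else:
        strata = np.asarray(strata)
        if strata.size != n:
            raise ValueError("strata do not align with the matrix")
        groups_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for b in range(1, n_perm + 1):
            mask = base.copy()
            for idx in groups_idx:
                mask[idx] = mask[idx[rng.permutation(idx.size)]]
            perm_masks[b] = mask
    ss_within = _pseudo_f_terms(d2, perm_masks)
    f_all = (ss_total - ss_within) / (ss_within / df_within)
    f_obs = float(f_all[0])
    n_ge = int(np.sum(f_all[1:] >= f_obs))
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_f=f_obs,
        p=float(p),
        n_permutations=n_perm,
        groups=(str(groups[0]), str(groups[1])),
    )


def study_permanova(
    study: StudyTable,
    comparison: str,
    n_perm: int = 999,
    seed: int = 0,
    use_relative: bool = True,
) -> PermanovaResult:
    """Per-study PERMANOVA of control vs one case group.

    Matched studies get within-subject permutation strata automatically.
    """
    sub = study.comparison_subset(comparison)
    dist = bray_curtis_matrix(sub, use_relative=use_relative)
    labels = sub.diagnoses()
    strata = None
    if sub.meta is not None and any(m.matched for m in sub.meta):
        strata = np.array([m.subject_id for m in sub.meta])
    return permanova(dist, labels, n_perm=n_perm, seed=seed, strata=strata)
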