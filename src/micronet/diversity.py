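"""Alpha diversity, Bray-Curtis beta diversity, PCoA and ANOSIM.

Chao1 and Shannon are computed per sample on the abundant / rare
sub-tables; community differences among successional stages are tested
with ANOSIM on Bray-Curtis distances and pairwise rank-sum tests on the
alpha indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, rankdata

from .errors import ValidationError


@dataclass
class DistanceMatrix:
    """Square symmetric non-negative distance matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValidationError("distance matrix size does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if d.size and d.min() < -1e-12:
            raise ValidationError("distances must be non-negative")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]


@dataclass
class OrdinationResult:
    coordinates: np.ndarray          # samples x axes (positive axes only)
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # per returned axis
    sample_ids: list[str]


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 / F2 are the singleton / doubleton counts; the estimate is always
    >= observed richness and reduces to it when no singletons exist.
    """
    c = np.asarray(counts)
    if c.size == 0 or c.max() <= 0:
        raise ValidationError("chao1 requires at least one positive count")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p ln p over positive proportions (nats by
    default; pass base=2 for bits)."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.max() <= 0:
        raise ValidationError("shannon requires at least one positive count")
    p = c[c > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def bray_curtis(mat, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(a,b) = sum|a-b| / sum(a+b)."""
    from .io_tables import AsvTable
    if isinstance(mat, AsvTable):
        sample_ids = list(mat.sample_ids)
        mat = mat.counts
    x = np.asarray(mat, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("bray_curtis needs at least two samples")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValidationError("two all-zero samples have undefined distance")
    ids = sample_ids if sample_ids is not None else \
        [f"sample_{i}" for i in range(x.shape[0])]
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")), list(ids))


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean distances) are reported but
    contribute no coordinates; no Lingoes/Cailliez correction is applied.
    """
    d = dist.data
    n = dist.n
    b = -0.5 * d ** 2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive "
                      "eigenvalues; clipping")
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    denom = eigval[pos].sum() if n_pos else 1.0
    prop = eigval[:n_axes] / denom
    return OrdinationResult(coords, eigval, prop, list(dist.ids))


def _pair_masks(groups: np.ndarray):
    n = len(groups)
    iu0, iu1 = np.triu_indices(n, k=1)
    return iu0, iu1, groups[iu0] == groups[iu1]


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """One-way analysis of similarity.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    midranks over all M = n(n-1)/2 pairwise distances; the one-sided
    permutation p-value uses the plus-one estimator.
    """
    g = np.asarray([str(x) for x in groups])
    if len(g) != dist.n:
        raise ValidationError("group labels do not match distance matrix")
    labs, counts = np.unique(g, return_counts=True)
    if len(labs) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        raise ValidationError("every group needs at least two samples")
    ranks = rankdata(dist.condensed())
    iu0, iu1, _ = _pair_masks(np.arange(dist.n))
    m = len(ranks)

    def stat(labels):
        within = labels[iu0] == labels[iu1]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = float(stat(g))
    rng = np.random.default_rng(seed)
    perm_labels = np.array([rng.permutation(g) for _ in range(n_perm)])
    within_perm = perm_labels[:, iu0] == perm_labels[:, iu1]
    sums_w = np.where(within_perm, ranks, 0.0).sum(axis=1)
    n_w = within_perm.sum(axis=1)
    sums_b = ranks.sum() - sums_w
    r_perm = (sums_b / (m - n_w) - sums_w / n_w) / (m / 2.0)
    p = (1.0 + np.sum(r_perm >= r_obs)) / (n_perm + 1.0)
    return r_obs, float(p)


def group_compare(values, groups) -> pd.DataFrame:
    """Pairwise two-sided rank-sum (Wilcoxon/Mann-Whitney) tests.

    Exact null distribution for small untied samples, normal
    approximation otherwise; returns one row per group pair.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    labs, counts = np.unique(g, return_counts=True)
    if counts.min() < 3:
        raise ValidationError("every group needs at least three samples")
    rows = []
    for a, b in combinations(labs, 2):
        xa, xb = v[g == a], v[g == b]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            warnings.warn(f"groups {a!r} and {b!r} are identical constants")
            p = 1.0
        else:
            p = float(mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="auto").pvalue)
        rows.append({"group_a": a, "group_b": b, "p_value": p})
    return pd.DataFrame(rows)


def diversity_report(table, partition, classes=("abundant", "rare")) -> pd.DataFrame:
    """Per-sample Chao1/Shannon on each abundance-class sub-table."""
    rows = []
    for cls in classes:
        taxa = partition.taxa_in_class(cls, retained_only=False)
        if not taxa:
            continue
        sub = table.subset_taxa(taxa)
        for i, sid in enumerate(sub.sample_ids):
            c = sub.counts[i]
            if c.max() <= 0:
                continue
            rows.append({"sample": sid, "class": cls,
                         "chao1": chao1(c), "shannon": shannon(c)})
    return pd.DataFrame(rows, columns=["sample", "class", "chao1", "shannon"])
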