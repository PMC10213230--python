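"""Abundance-class partitioning and prevalence filtering.

Taxa with mean relative abundance above 0.1% are "abundant", below 0.01%
"rare", and everything in between "intermediate" (excluded from both
networks).  Only taxa present in strictly more than half of the samples
used for a given network are retained for network construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import AsvTable

ABUNDANT_CUT = 1e-3   # fraction scale (0.1%)
RARE_CUT = 1e-4       # fraction scale (0.01%)


@dataclass
class AbundancePartition:
    taxon_ids: list[str]
    mean_rel_abund: np.ndarray
    labels: np.ndarray          # 'abundant' | 'rare' | 'intermediate'
    prevalence: np.ndarray      # fraction of samples with count > 0
    retained: np.ndarray        # bool, prevalence strictly > min_frac

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon_id": self.taxon_ids,
            "mean_rel_abund": self.mean_rel_abund,
            "class": self.labels,
            "prevalence": self.prevalence,
            "retained": self.retained,
        }).set_index("taxon_id")

    def taxa_in_class(self, label: str, retained_only: bool = True) -> list[str]:
        mask = self.labels == label
        if retained_only:
            mask &= self.retained
        return [t for t, m in zip(self.taxon_ids, mask) if m]


def relative_abundance(table: AsvTable) -> np.ndarray:
    """Row-normalize counts to fractions (each sample sums to 1)."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    return table.counts / totals[:, None]


def classify_abundance(table: AsvTable, abundant_cut: float = ABUNDANT_CUT,
                       rare_cut: float = RARE_CUT,
                       sample_ids: list[str] | None = None) -> AbundancePartition:
    """Label taxa by mean relative abundance across samples.

    The mean is taken over all samples of the dataset (or the subset
    ``sample_ids``, for stage-scoped classification).  Cutoffs are strict:
    abundant iff mean > abundant_cut, rare iff mean < rare_cut.
    """
    if not 0 < rare_cut < abundant_cut < 1:
        raise ValidationError("need 0 < rare_cut < abundant_cut < 1")
    sub = table if sample_ids is None else table.subset_samples(sample_ids)
    rel = relative_abundance(sub)
    mean_rel = rel.mean(axis=0)
    labels = np.where(mean_rel > abundant_cut, "abundant",
                      np.where(mean_rel < rare_cut, "rare", "intermediate"))
    prevalence = (sub.counts > 0).mean(axis=0)
    return AbundancePartition(list(table.taxon_ids), mean_rel, labels,
                              prevalence, prevalence > 0.5)


def prevalence_filter(partition: AbundancePartition, table: AsvTable,
                      min_frac: float = 0.5,
                      sample_ids: list[str] | None = None) -> AbundancePartition:
    """Recompute prevalence (optionally within a stage's sample set) and
    set the retained flag with a strict > ``min_frac`` rule."""
    if partition.taxon_ids != table.taxon_ids:
        raise ValidationError("partition does not match table taxa")
    if not 0 <= min_frac < 1:
        raise ValidationError("min_frac must lie in [0, 1)")
    sub = table if sample_ids is None else table.subset_samples(sample_ids)
    if sub.n_samples == 0:
        warnings.warn("prevalence filter applied to an empty sample set")
    prevalence = (sub.counts > 0).mean(axis=0) if sub.n_samples else \
        np.zeros(table.n_taxa)
    return AbundancePartition(partition.taxon_ids, partition.mean_rel_abund,
                              partition.labels, prevalence,
                              prevalence > min_frac)
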