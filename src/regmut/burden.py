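"""Cohort filtering and per-window somatic mutation burden.

Regional mutation burden is the number of somatic SNVs per fixed-size
genomic window per cancer cohort. Hypermutated genomes (more than 90,000
SNVs, roughly 30 mutations/Mbp) are removed before counting because they
would otherwise dominate regional estimates, and only cohorts with at
least 25 genomes are analysed individually; a pan-cancer pseudo-cohort
pooling every retained sample is always produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import WindowGrid

logger = logging.getLogger(__name__)

PAN_CANCER = "Pan-cancer"

#: Default hypermutator threshold: samples with MORE than this many SNVs
#: are excluded (a sample at exactly the threshold is kept).
MAX_SNVS_PER_SAMPLE = 90_000

#: Minimum cohort size for per-cancer-type analysis.
MIN_COHORT_SAMPLES = 25

#: Immunoglobulin-locus windows (chrom, start of the containing 1-Mbp
#: window) excluded for lymphoid cohorts, where somatic hypermutation
#: inflates local burden independently of chromatin state.
IG_REGIONS_1MB = (("chr2", 89_000_000), ("chr22", 23_000_000))

#: Cohorts for which the immunoglobulin exclusion applies.
LYMPHOID_COHORTS = ("CLL", "Lymph-CLL", "BNHL", "Lymph-BNHL")


@dataclass
class BurdenVector:
    """Per-window mutation response for one cohort.

    ``mutation_class`` is ``"all"`` for total SNV counts or an SBS
    signature id for probabilistic signature-specific burden (then
    counts are non-negative reals rather than integers).
    """

    cohort: str
    mutation_class: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("burden counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def per_sample_counts(snvs: pd.DataFrame) -> pd.Series:
    return snvs.groupby("sample_id").size()


def filter_hypermutators(
    counts: pd.Series, max_snvs: int = MAX_SNVS_PER_SAMPLE
) -> set[str]:
    """Samples kept after removing hypermutators (strictly more than
    ``max_snvs`` SNVs; equality is kept)."""
    if (counts < 0).any():
        raise ValueError("negative SNV counts")
    kept = set(counts.index[counts <= max_snvs])
    n_removed = len(counts) - len(kept)
    if n_removed:
        logger.info("removed %d hypermutated samples (> %d SNVs)", n_removed, max_snvs)
    return kept


def select_cohorts(
    cohort_sizes: pd.Series, min_samples: int = MIN_COHORT_SAMPLES
) -> list[str]:
    """Cohorts analysed individually (>= ``min_samples`` genomes), plus
    the pan-cancer pool, which always appears first and includes every
    sample regardless of its cohort's size."""
    kept = sorted(cohort_sizes.index[cohort_sizes >= min_samples])
    return [PAN_CANCER] + kept


def apply_sample_filters(
    snvs: pd.DataFrame,
    max_snvs: int = MAX_SNVS_PER_SAMPLE,
    min_samples: int = MIN_COHORT_SAMPLES,
) -> tuple[pd.DataFrame, list[str]]:
    """Hypermutator removal followed by cohort selection.

    Returns the filtered SNV table (hypermutators dropped; all samples
    retained for the pan-cancer pool) and the cohort list.
    """
    kept = filter_hypermutators(per_sample_counts(snvs), max_snvs)
    snvs = snvs[snvs["sample_id"].isin(kept)]
    sizes = snvs.groupby("cohort")["sample_id"].nunique()
    return snvs.reset_index(drop=True), select_cohorts(sizes, min_samples)


def count_burden(snvs: pd.DataFrame, grid: WindowGrid, cohort: str) -> BurdenVector:
    """Total SNV count per window for one cohort.

    ``cohort`` may be :data:`PAN_CANCER` to pool all records. SNV
    positions are 1-based and assigned to the window containing
    ``pos - 1`` in 0-based half-open coordinates; SNVs outside any kept
    window (filtered, excluded, or unknown chromosome) are skipped and
    tallied in a log line.
    """
    sub = snvs if cohort == PAN_CANCER else snvs[snvs["cohort"] == cohort]
    counts = np.zeros(len(grid), dtype=float)
    if len(sub):
        unknown = ~sub["chrom"].isin(set(grid.chroms))
        if unknown.any():
            logger.warning(
                "%s: skipped %d SNVs on chromosomes absent from the grid",
                cohort,
                int(unknown.sum()),
            )
            sub = sub[~unknown]
        idx = grid.window_index(
            sub["chrom"].to_numpy(dtype=object), sub["pos"].to_numpy() - 1
        )
        skipped = int((idx < 0).sum())
        if skipped:
            logger.info("%s: %d SNVs fall outside kept windows", cohort, skipped)
        np.add.at(counts, idx[idx >= 0], 1.0)
    return BurdenVector(cohort=cohort, mutation_class="all", counts=counts)
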