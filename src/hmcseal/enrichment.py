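"""Ranked-list overlap enrichment and the neighbor-correlation null.

Two comparisons recur in the analysis: (i) whether genes at the top of
one ranking (say, cfDNA log2 fold change in cancer) are over-represented
at the top of another (tissue 5hmC level), measured as a percentile-
overlap fold with a one-sided Fisher's exact test; and (ii) whether
cancer-associated 5hmC changes are spatially autocorrelated along the
chromosome, assessed against a null built by shuffling gene positions
within each chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    percentile: float
    n_universe: int
    n_list_a: int
    n_list_b: int
    n_overlap: int
    fold: float
    fisher_p: float


def _top_set(ranking: pd.Series, k: int) -> set[str]:
    # descending by value; ties broken by stable gene-id order
    ordered = ranking.sort_index().sort_values(ascending=False, kind="stable")
    return set(ordered.index[:k])


def percentile_enrichment(
    rank_a: pd.Series,
    rank_b: pd.Series,
    percentile: float,
    universe: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Overlap enrichment of the top-percentile sets of two rankings.

    fold = (|A ∩ B| * N) / (|A| * |B|); the p-value is the one-sided
    Fisher's exact (hypergeometric upper tail) for the 2x2 overlap
    table. Set sizes are ceil(percentile/100 * N).
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    if universe is None:
        universe = sorted(set(rank_a.index) & set(rank_b.index))
    universe = list(universe)
    N = len(universe)
    k = math.ceil(percentile / 100.0 * N)
    if k == 0 or N == 0:
        raise ValueError("percentile yields an empty set")
    a = _top_set(rank_a.loc[universe], k)
    b = _top_set(rank_b.loc[universe], k)
    overlap = len(a & b)
    fold = overlap * N / (len(a) * len(b))
    # P(X >= overlap), X ~ Hypergeom(N, |A|, |B|)
    p = float(stats.hypergeom.sf(overlap - 1, N, len(a), len(b)))
    return EnrichmentResult(
        percentile=percentile,
        n_universe=N,
        n_list_a=len(a),
        n_list_b=len(b),
        n_overlap=overlap,
        fold=fold,
        fisher_p=p,
    )


@dataclass
class NeighborNull:
    observed_r: float
    null_r: np.ndarray
    empirical_p: float
    n_shuffle: int
    seed: int


def _neighbor_pairs(values: np.ndarray, chrom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(gene, next-gene) value pairs within chromosomes, in positional order."""
    left, right = [], []
    for c in pd.unique(chrom):
        v = values[chrom == c]
        if len(v) >= 2:
            left.append(v[:-1])
            right.append(v[1:])
    if not left:
        raise ValueError("no chromosome has >= 2 genes")
    return np.concatenate(left), np.concatenate(right)


def neighbor_correlation(values: np.ndarray, chrom: np.ndarray) -> float:
    """Pearson correlation between neighboring genes' values within chromosomes."""
    a, b = _neighbor_pairs(values, chrom)
    if len(a) < 2:
        raise ValueError("need at least 2 neighbor pairs")
    return float(np.corrcoef(a, b)[0, 1])


def neighbor_correlation_null(
    log2fc: Sequence[float] | pd.Series,
    chrom: Sequence[str],
    n_shuffle: int = 1000,
    seed: int = 0,
) -> NeighborNull:
    """Permutation null for the neighbor correlation of per-gene changes.

    Positions are shuffled independently within each chromosome
    ``n_shuffle`` times; the add-one empirical p-value is
    (1 + #{null >= observed}) / (1 + n_shuffle).
    """
    if n_shuffle < 1:
        raise ValueError("n_shuffle must be >= 1")
    values = np.asarray(log2fc, dtype=float)
    chrom = np.asarray(list(chrom))
    for c in pd.unique(chrom):
        if (chrom == c).sum() < 3:
            raise ValueError(f"chromosome {c} has fewer than 3 genes")
    observed = neighbor_correlation(values, chrom)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    shuffled = values.copy()
    idx_by_chrom = [np.where(chrom == c)[0] for c in pd.unique(chrom)]
    for s in range(n_shuffle):
        for idx in idx_by_chrom:
            shuffled[idx] = values[idx][rng.permutation(len(idx))]
        null[s] = neighbor_correlation(shuffled, chrom)
    p = (1 + int((null >= observed).sum())) / (1 + n_shuffle)
    return NeighborNull(
        observed_r=observed, null_r=null, empirical_p=p, n_shuffle=n_shuffle, seed=seed
    )


def correlate_fold_changes(
    fc_a: pd.Series,
    fc_b: pd.Series,
    gene_subset: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of two per-gene fold-change vectors over a subset.

    Returns (r, two-sided t-test p). Requires at least 3 shared genes
    and nonzero variance in both vectors.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a fold-change vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
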