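"""Classifier evaluation: ROC/AUC, best cutoff, stage trend, clustering.

Covers the performance summaries used for the cancer classifier:
ROC curves and AUC, sensitivity/specificity at the cutoff maximizing
their sum (the Youden point), cancer-call rates by group, the
Cochran-Armitage trend test for call proportions across ordered stage
groups, and correlation-distance average-linkage sample clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.metrics import roc_curve


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and trapezoidal AUC.

    AUC equals the probability that a random positive outscores a
    random negative, counting ties one half. Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def sens_spec_best(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity (calls are score > cutoff).

    All midpoints between adjacent distinct scores are evaluated, plus
    boundary cutoffs; ties in the sum are broken toward higher
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for c in cuts:
        called = scores > c
        sens = (called & (labels == 1)).sum() / n_pos
        spec = (~called & (labels == 0)).sum() / n_neg
        key = (sens + spec, sens)
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    assert best is not None
    return best[1], best[2], best[3]


@dataclass
class TrendTable:
    """Ordered binomial proportions: calls per group across ordered groups."""

    groups: list[str]
    n_called: np.ndarray
    n_total: np.ndarray
    scores: np.ndarray | None = None  # defaults to 0, 1, 2, ...

    def __post_init__(self) -> None:
        self.n_called = np.asarray(self.n_called, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=float)
        if len(self.groups) < 2:
            raise ValueError("need at least 2 ordered groups")
        if ((self.n_called < 0) | (self.n_called > self.n_total)).any():
            raise ValueError("require 0 <= n_called <= n_total per group")
        if self.scores is None:
            self.scores = np.arange(len(self.groups), dtype=float)
        else:
            self.scores = np.asarray(self.scores, dtype=float)


def cochran_armitage_trend(table: TrendTable) -> tuple[float, float]:
    """Cochran-Armitage test for a monotone trend in proportions.

    T = sum_i x_i (r_i - n_i pbar); Var T = pbar (1 - pbar)
    [sum n_i x_i^2 - (sum n_i x_i)^2 / N]; z = T / sqrt(Var T); the
    p-value is two-sided from the standard normal.
    """
    x, r, n = table.scores, table.n_called, table.n_total
    N = n.sum()
    if N < 4:
        raise ValueError("need total n >= 4")
    pbar = r.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("degenerate table: pooled proportion is 0 or 1")
    T = float(np.sum(x * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * x**2) - np.sum(n * x) ** 2 / N)
    if var <= 0:
        raise ValueError("zero trend variance (identical scores?)")
    z = T / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def cochran_armitage_permutation(
    table: TrendTable, n_permutations: int = 10000, seed: int = 0
) -> float:
    """Permutation p-value for the trend statistic (two-sided), as an
    exact-flavored alternative to the normal approximation."""
    rng = np.random.default_rng(seed)
    x, r, n = table.scores, table.n_called, table.n_total
    N = int(n.sum())
    pool = np.zeros(N)
    pool[: int(r.sum())] = 1.0
    group_idx = np.repeat(np.arange(len(n)), n.astype(int))
    pbar = r.sum() / N

    def stat(assign: np.ndarray) -> float:
        rr = np.bincount(group_idx, weights=assign, minlength=len(n))
        return float(np.sum(x * (rr - n * pbar)))

    obs = float(np.sum(x * (r - n * pbar)))
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        if abs(stat(pool)) >= abs(obs) - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def call_rate(
    calls: Sequence[int] | Sequence[bool], grouping: Sequence[str]
) -> pd.Series:
    """Fraction of positive calls per group."""
    df = pd.DataFrame({"call": np.asarray(calls, dtype=float), "group": list(grouping)})
    sizes = df.groupby("group").size()
    if (sizes == 0).any():
        raise ValueError("empty group")
    return df.groupby("group")["call"].mean()


@dataclass
class ClusterResult:
    linkage: np.ndarray
    order: list[int]
    labels: list[str]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]


def corr_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of samples under correlation distance.

    ``matrix`` is samples x features; distance is 1 - Pearson r.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    V = matrix.to_numpy(dtype=float)
    sd = V.std(axis=1)
    if (sd == 0).any():
        bad = matrix.index[sd == 0].tolist()
        raise ValueError(f"zero-variance samples: {bad}")
    corr = np.corrcoef(V)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(linkage=Z, order=order, labels=list(matrix.index))
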