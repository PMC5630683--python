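"""End-to-end biomarker discovery -> training -> prediction pipeline.

Chains the analysis the way it runs on a real cohort: differential
testing on the discovery batch, locus selection at 5% FDR and a
1.2-fold floor, rlog normalization frozen to the discovery batch,
penalty factors from the discovery log2 fold changes, elastic-net
training with alpha chosen on a disjoint validation batch, and scoring
of held-out samples against the frozen model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ElasticNetModel, penalty_factors, predict, select_alpha
from .differential import (
    DesignSpec,
    nb_wald_test,
    rlog_apply,
    rlog_fit,
    select_differential,
)
from .features import CountMatrix


@dataclass
class PipelineResult:
    model: ElasticNetModel
    alpha: float
    alpha_table: pd.DataFrame
    differential: pd.DataFrame
    selected_features: list[str]
    validation_auc: float


def status_labels(matrix: CountMatrix, positive: str = "cancer") -> np.ndarray:
    return (matrix.metadata["status"] == positive).to_numpy(dtype=float)


def train_pipeline(
    discovery: CountMatrix,
    validation: CountMatrix,
    design: DesignSpec | None = None,
    contrast: tuple[str, str, str] = ("status", "cancer", "healthy"),
    fdr: float = 0.05,
    fold: float = 1.2,
    alpha_grid=None,
    n_folds: int = 10,
    seed: int = 0,
) -> PipelineResult:
    """Run discovery -> select -> rlog-freeze -> weighted elastic net."""
    design = design or DesignSpec()
    diff = nb_wald_test(discovery, design, contrast)
    selected = select_differential(diff, fdr=fdr, fold=fold)
    if len(selected) == 0:
        raise ValueError("no differential features selected; cannot train")
    disc_sel = discovery.subset_features(selected)
    reference, train_values = rlog_fit(disc_sel)
    val_values = rlog_apply(validation.subset_features(selected), reference)
    nu = penalty_factors(diff.loc[selected, "log2fc"])
    y_train = status_labels(discovery)
    y_val = status_labels(validation)
    kwargs = {} if alpha_grid is None else {"alpha_grid": alpha_grid}
    alpha, model, table = select_alpha(
        (train_values, y_train),
        (val_values, y_val),
        nu,
        n_folds=n_folds,
        seed=seed,
        reference=reference,
        **kwargs,
    )
    best_auc = float(table.loc[table["alpha"] == alpha, "validation_auc"].iloc[0])
    return PipelineResult(
        model=model,
        alpha=alpha,
        alpha_table=table,
        differential=diff,
        selected_features=selected,
        validation_auc=best_auc,
    )


def score_cohort(result: PipelineResult, cohort: CountMatrix) -> pd.DataFrame:
    """Score a held-out cohort with the frozen model."""
    return predict(result.model, cohort.subset_features(result.selected_features))
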