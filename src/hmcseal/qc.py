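"""Spike-in capture QC: enrichment ratios and input-mass linearity.

A pair of synthetic probes — one carrying 5hmC, one without — is added
at fixed mass to each library. The ratio of captured 5hmC-probe to
no5hmC-probe reads measures pull-down selectivity; comparing the
experimental (pull-down) group ratio to the control (no pull-down)
group ratio gives the enrichment fold. Titrating probe concentration
against cfDNA input mass checks quantitative capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SPIKEIN_COLUMNS = (
    "library_id",
    "group",
    "input_mass_ng",
    "spike_mass_fg",
    "reads_5hmc_probe",
    "reads_no5hmc_probe",
    "total_reads",
)


def spikein_ratio(reads_5hmc: int, reads_no5hmc: int) -> float:
    """Ratio of 5hmC-probe to no5hmC-probe reads in one library."""
    if reads_no5hmc <= 0:
        raise ZeroDivisionError("no5hmC probe read count must be positive")
    return reads_5hmc / reads_no5hmc


def enrichment_fold(ratio_experimental: float, ratio_control: float) -> float:
    """Fold enrichment of the pull-down group over the no-pull-down control."""
    if ratio_control <= 0:
        raise ValueError("control ratio must be positive")
    return ratio_experimental / ratio_control


def group_ratios(table: pd.DataFrame, pooled: bool = False) -> pd.Series:
    """Per-group spike ratios: mean of per-library ratios (default) or the
    pooled-read ratio."""
    if pooled:
        g = table.groupby("group")[["reads_5hmc_probe", "reads_no5hmc_probe"]].sum()
        return g["reads_5hmc_probe"] / g["reads_no5hmc_probe"]
    ratios = table["reads_5hmc_probe"] / table["reads_no5hmc_probe"]
    return ratios.groupby(table["group"].values).mean()


def table_enrichment_fold(table: pd.DataFrame, pooled: bool = False) -> float:
    """Enrichment fold from a spike-in table with control and experimental groups."""
    r = group_ratios(table, pooled=pooled)
    for g in ("experimental", "control"):
        if g not in r.index:
            raise ValueError(f"missing group {g!r} in spike-in table")
    return enrichment_fold(float(r["experimental"]), float(r["control"]))


@dataclass
class LinearityResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


def spikein_linearity(table: pd.DataFrame) -> LinearityResult:
    """OLS of the 5hmC-probe read proportion on spike concentration.

    Concentration is spike mass over cfDNA input mass (fg/ng); the
    response is reads_5hmc_probe / total_reads. Requires at least three
    distinct input masses.
    """
    conc = (table["spike_mass_fg"] / table["input_mass_ng"]).to_numpy(dtype=float)
    prop = (table["reads_5hmc_probe"] / table["total_reads"]).to_numpy(dtype=float)
    if len(np.unique(np.round(conc, 12))) < 3:
        raise ValueError("need at least 3 distinct spike concentrations")
    if np.ptp(prop) == 0.0:  # constant response: no explainable variance
        return LinearityResult(0.0, 0.0, float(prop[0]), len(prop))
    fit = stats.linregress(conc, prop)
    return LinearityResult(float(fit.rvalue**2), float(fit.slope), float(fit.intercept), len(prop))


def read_spikein_table(path) -> pd.DataFrame:
    """Read a spike-in TSV and validate the required columns."""
    table = pd.read_csv(path, sep="\t")
    missing = set(SPIKEIN_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spike-in table missing columns: {sorted(missing)}")
    if (table[["input_mass_ng", "spike_mass_fg"]] <= 0).any().any():
        raise ValueError("masses must be positive")
    if (table["reads_5hmc_probe"] + table["reads_no5hmc_probe"] > table["total_reads"]).any():
        raise ValueError("probe reads exceed total reads")
    return table
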