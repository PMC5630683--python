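"""Synthetic cfDNA 5hmC cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: per-gene hydroxymethylation levels with a variance hierarchy
locus > tissue > disease; cancer plasma cfDNA as a small tumor-fraction
mixture over a healthy background; negative-binomial counting noise with
per-sample library sizes; multiplicative per-technician batch effects;
and chromosomal (AR(1)) autocorrelation of effects along gene order.

Effects live on the natural-log scale; the tumor/background mixture is
applied on the natural scale before count sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    CountMatrix,
    FeatureCatalog,
    Fragment,
    GenomicInterval,
    METADATA_COLUMNS,
)

DEFAULT_TISSUES = ("background", "tumor_site")


@dataclass
class EffectTables:
    """Per-gene hierarchical effects on the natural-log scale."""

    gene_ids: list[str]
    gene_chrom: np.ndarray  # chromosome label per gene, in chromosomal order
    locus_effect: np.ndarray
    tissue_effect: pd.DataFrame  # genes x tissues
    disease_effect: np.ndarray
    ar1_rho: float
    sigma_locus: float
    sigma_tissue: float
    sigma_disease: float

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if not (len(self.locus_effect) == len(self.disease_effect) == len(self.tissue_effect) == n):
            raise ValueError("effect tables have inconsistent gene dimension")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def disease_genes(self) -> list[str]:
        return [g for g, d in zip(self.gene_ids, self.disease_effect) if d != 0.0]


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.

    Tumor fractions for cancer samples default to Uniform(0.05, 0.2),
    sorted so that fraction increases with TNM-like stage label; controls
    are always fraction 0.
    """

    n_cancer: int = 15
    n_control: int = 18
    tumor_fraction: np.ndarray | None = None  # per cancer sample; drawn if None
    tumor_fraction_range: tuple[float, float] = (0.05, 0.2)
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.2  # lognormal sd of library sizes
    nb_dispersion: float = 0.05
    batch_sd: float = 0.15
    n_technicians: int = 2
    stage_labels: tuple[str, ...] = ("I", "II-III", "IV")
    cancer_type: str = "colorectal"
    batch: str = "batch1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.library_size_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("library_size_mean and nb_dispersion must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        if self.tumor_fraction is not None:
            tf = np.asarray(self.tumor_fraction, dtype=float)
            if ((tf < 0) | (tf > 1)).any():
                raise ValueError("tumor_fraction must lie in [0, 1]")
            self.tumor_fraction = tf


@dataclass
class SpikeInDesign:
    """Spike-in probe experiment: fixed probe mass against varying cfDNA input."""

    copies_per_probe: int = 100_000_000
    input_mass_ng: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 20.0)
    spike_mass_fg: float = 2.6
    capture_efficiency_hmc: float = 0.9
    capture_efficiency_nohmc: float = 0.0225
    total_reads: int = 20_000_000
    spike_read_scale: float = 4000.0  # expected spike reads per fg at 1 ng input

    def __post_init__(self) -> None:
        if self.copies_per_probe <= 0:
            raise ValueError("copies_per_probe must be positive")
        if self.spike_mass_fg <= 0 or any(m <= 0 for m in self.input_mass_ng):
            raise ValueError("masses must be positive")
        if not (0 < self.capture_efficiency_nohmc <= self.capture_efficiency_hmc <= 1):
            raise ValueError("require 0 < capture_efficiency_nohmc <= capture_efficiency_hmc <= 1")


# ---------------------------------------------------------------------------
# Catalog


def generate_catalog(
    n_chrom: int,
    genes_per_chrom: int,
    peak_categories: Sequence[str] = (),
    seed: int = 0,
    gene_length_range: tuple[int, int] = (2_000, 20_000),
    gap_range: tuple[int, int] = (1_000, 10_000),
    peaks_per_chrom: int = 200,
) -> FeatureCatalog:
    """Lay out non-overlapping gene bodies along synthetic chromosomes.

    Emits gene bodies, one promoter per gene (3 kb upstream, strand
    aware), and one random peak set per requested category.
    """
    if n_chrom < 1 or genes_per_chrom < 2:
        raise ValueError("need n_chrom >= 1 and genes_per_chrom >= 2")
    rng = np.random.default_rng(seed)
    genes: list[GenomicInterval] = []
    chrom_len: dict[str, int] = {}
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        pos = 10_000
        for g in range(genes_per_chrom):
            gap = int(rng.integers(*gap_range))
            length = int(rng.integers(*gene_length_range))
            start = pos + gap
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GenomicInterval(chrom, start, start + length, f"{chrom}_g{g:04d}", strand)
            )
            pos = start + length
        chrom_len[chrom] = pos + 10_000

    from .features import derive_features

    catalog = derive_features(genes)
    for cat in peak_categories:
        peaks = []
        for chrom, L in chrom_len.items():
            starts = np.sort(rng.integers(0, L - 2_000, size=peaks_per_chrom))
            widths = rng.integers(200, 2_000, size=peaks_per_chrom)
            for i, (s, w) in enumerate(zip(starts, widths)):
                peaks.append(
                    GenomicInterval(chrom, int(s), int(s + w), f"{cat}_{chrom}_p{i:04d}")
                )
        catalog.add_category(cat, peaks)
    return catalog


# ---------------------------------------------------------------------------
# Effects


def _ar1_field(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal sd sigma."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, 1.0, size=n - 1) if n > 1 else np.empty(0)
    scale = (1.0 - rho * rho) ** 0.5
    for i in range(1, n):
        x[i] = rho * x[i - 1] + scale * innov[i - 1]
    return sigma * x


def simulate_effects(
    catalog: FeatureCatalog,
    sigma_locus: float = 1.5,
    sigma_tissue: float = 0.8,
    sigma_disease: float = 0.5,
    ar1_rho: float = 0.7,
    n_disease_genes: int = 0,
    seed: int = 0,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    disease_block_mean: int = 8,
) -> EffectTables:
    """Draw hierarchical per-gene effects with AR(1) chromosomal correlation.

    Locus and disease effects follow an AR(1) process along gene order
    within each chromosome (lag-1 correlation ``ar1_rho``); tissue
    effects are drawn per tissue. Disease effects are nonzero on exactly
    ``n_disease_genes`` genes, placed in contiguous blocks so the
    nonzero field keeps its autocorrelation; signs are mixed.
    """
    if not (0.0 <= ar1_rho < 1.0):
        raise ValueError("ar1_rho must lie in [0, 1)")
    if min(sigma_locus, sigma_tissue, sigma_disease) <= 0:
        raise ValueError("sigmas must be positive")
    genes = catalog.intervals("gene_bodies")
    gene_ids = [g.id for g in genes]
    gene_chrom = np.array([g.chrom for g in genes])
    n = len(genes)
    if n_disease_genes > n:
        raise ValueError("n_disease_genes exceeds total genes")
    rng = np.random.default_rng(seed)

    def per_chrom_field(sigma: float) -> np.ndarray:
        out = np.empty(n)
        for chrom in pd.unique(gene_chrom):
            idx = np.where(gene_chrom == chrom)[0]
            out[idx] = _ar1_field(rng, len(idx), ar1_rho, sigma)
        return out

    locus = per_chrom_field(sigma_locus)
    tissue = pd.DataFrame(
        {t: per_chrom_field(sigma_tissue) for t in tissues}, index=gene_ids
    )
    disease_field = per_chrom_field(sigma_disease)
    disease = np.zeros(n)
    if n_disease_genes > 0:
        mask = np.zeros(n, dtype=bool)
        order = rng.permutation(n)
        k = 0
        need = n_disease_genes
        while need > 0 and k < n:
            start = order[k]
            k += 1
            if mask[start]:
                continue
            block = 1 + rng.geometric(1.0 / disease_block_mean)
            stop = min(n, start + block)
            take = np.arange(start, stop)[~mask[start:stop]][:need]
            mask[take] = True
            need -= len(take)
        vals = disease_field[mask]
        # ensure strictly nonzero (prob-0 event, but the invariant is exact)
        vals[vals == 0.0] = sigma_disease
        disease[mask] = vals
    return EffectTables(
        gene_ids=gene_ids,
        gene_chrom=gene_chrom,
        locus_effect=locus,
        tissue_effect=tissue,
        disease_effect=disease,
        ar1_rho=ar1_rho,
        sigma_locus=sigma_locus,
        sigma_tissue=sigma_tissue,
        sigma_disease=sigma_disease,
    )


# ---------------------------------------------------------------------------
# Cohorts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_mean_profile(
    effects: EffectTables,
    tumor_fraction: float,
    background_tissue: str = "background",
    tumor_tissue: str = "tumor_site",
) -> np.ndarray:
    """Natural-scale relative abundance of a plasma sample at fraction phi."""
    base = effects.locus_effect
    bg = np.exp(base + effects.tissue_effect[background_tissue].to_numpy())
    tm = np.exp(
        base + effects.tissue_effect[tumor_tissue].to_numpy() + effects.disease_effect
    )
    return (1.0 - tumor_fraction) * bg + tumor_fraction * tm


def simulate_cohort(effects: EffectTables, config: SimulationConfig) -> CountMatrix:
    """Simulate a plasma cfDNA cohort of cancer patients and healthy controls.

    Cancer plasma at gene j has natural-scale mean
    (1 - phi) * background_j + phi * tumor_j; counts are negative
    binomial with per-sample library size and a per-technician
    multiplicative log-normal batch effect (sd ``batch_sd`` per gene).
    """
    rng = np.random.default_rng(config.seed)
    n_can, n_ctl = config.n_cancer, config.n_control
    n = n_can + n_ctl
    if n == 0:
        raise ValueError("empty cohort")
    if config.tumor_fraction is not None:
        if len(config.tumor_fraction) != n_can:
            raise ValueError("tumor_fraction length must equal n_cancer")
        phis = np.sort(np.asarray(config.tumor_fraction, dtype=float))
    else:
        lo, hi = config.tumor_fraction_range
        phis = np.sort(rng.uniform(lo, hi, size=n_can))
    # stage increases with tumor fraction
    stages = np.empty(n_can, dtype=object)
    if n_can:
        cuts = np.array_split(np.arange(n_can), len(config.stage_labels))
        for lab, idx in zip(config.stage_labels, cuts):
            stages[idx] = lab

    tech_labels = [f"tech{t+1}" for t in range(config.n_technicians)]
    tech_factor = {
        t: np.exp(rng.normal(0.0, config.batch_sd, size=effects.n_genes))
        for t in tech_labels
    }

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    order = rng.permutation(n)  # interleave cancer/control across technicians
    sample_specs = [("cancer", i) for i in range(n_can)] + [("healthy", i) for i in range(n_ctl)]
    for slot, pos in enumerate(order):
        status, i = sample_specs[pos]
        phi = float(phis[i]) if status == "cancer" else 0.0
        sid = f"{config.batch}_{status[:3]}{i:03d}"
        tech = tech_labels[slot % config.n_technicians]
        rel = _sample_mean_profile(effects, phi) * tech_factor[tech]
        rel = rel / rel.sum()
        lib = config.library_size_mean * np.exp(
            rng.normal(-0.5 * config.library_size_sigma**2, config.library_size_sigma)
        )
        cols[sid] = _nb_draw(rng, rel * lib, config.nb_dispersion)
        meta_rows.append(
            {
                "sample_id": sid,
                "status": status,
                "cancer_type": config.cancer_type if status == "cancer" else "none",
                "stage": stages[i] if status == "cancer" else "healthy",
                "age_group": str(rng.choice(["<20", "20-55", ">55"], p=[0.05, 0.45, 0.5])),
                "technician": tech,
                "batch": config.batch,
                "patient_id": f"{config.batch}_pt{pos:03d}",
                "tumor_fraction": phi,
            }
        )
    counts = pd.DataFrame(cols, index=effects.gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts, meta)


def simulate_tissue_pairs(
    effects: EffectTables, n_patients: int, config: SimulationConfig
) -> CountMatrix:
    """Simulate paired tumor / adjacent-tissue gDNA samples.

    Two samples per patient: the tumor carries the full disease effect
    (phi = 1); the adjacent tissue is the same tissue without it.
    Patients are nested under technicians (both samples of a patient are
    processed by the same technician).
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(config.seed + 1)
    tech_labels = [f"tech{t+1}" for t in range(config.n_technicians)]
    tech_factor = {
        t: np.exp(rng.normal(0.0, config.batch_sd, size=effects.n_genes))
        for t in tech_labels
    }
    base = effects.locus_effect + effects.tissue_effect["tumor_site"].to_numpy()
    adjacent_rel = np.exp(base)
    tumor_rel = np.exp(base + effects.disease_effect)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for p in range(n_patients):
        pid = f"{config.batch}_tpt{p:03d}"
        tech = tech_labels[p % config.n_technicians]
        for kind, rel, phi in (("tumor", tumor_rel, 1.0), ("adjacent", adjacent_rel, 0.0)):
            sid = f"{pid}_{kind}"
            r = rel * tech_factor[tech]
            r = r / r.sum()
            lib = config.library_size_mean * np.exp(
                rng.normal(-0.5 * config.library_size_sigma**2, config.library_size_sigma)
            )
            cols[sid] = _nb_draw(rng, r * lib, config.nb_dispersion)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "status": kind,
                    "cancer_type": config.cancer_type,
                    "stage": "NA",
                    "age_group": str(rng.choice(["<20", "20-55", ">55"], p=[0.05, 0.45, 0.5])),
                    "technician": tech,
                    "batch": config.batch,
                    "patient_id": pid,
                    "tumor_fraction": phi,
                }
            )
    counts = pd.DataFrame(cols, index=effects.gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# Spike-ins


def spikein_expected_proportions(
    design: SpikeInDesign, input_mass_ng: float, pulldown: bool
) -> tuple[float, float]:
    """Expected (5hmC-probe, no5hmC-probe) read proportions of a library.

    Reads are allocated proportionally to capture-weighted mass; without
    pull-down both probes and the genomic background are captured with
    the baseline efficiency.
    """
    eff_h = design.capture_efficiency_hmc if pulldown else design.capture_efficiency_nohmc
    eff_n = design.capture_efficiency_nohmc
    w_h = design.spike_mass_fg * eff_h * design.spike_read_scale
    w_n = design.spike_mass_fg * eff_n * design.spike_read_scale
    w_bg = input_mass_ng * 1e6 * eff_n
    total = w_h + w_n + w_bg
    return w_h / total, w_n / total


def simulate_spikein(
    design: SpikeInDesign,
    seed: int = 0,
    n_replicates: int = 3,
    groups: Sequence[str] = ("control", "experimental"),
) -> pd.DataFrame:
    """Simulate spike-in read tables for control (no pull-down) and
    experimental (pull-down) libraries over the configured cfDNA inputs.

    Returns the SpikeInTable layout: one row per library with columns
    library_id, group, input_mass_ng, spike_mass_fg, reads_5hmc_probe,
    reads_no5hmc_probe, total_reads.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        pulldown = group == "experimental"
        for mass in design.input_mass_ng:
            for rep in range(n_replicates):
                p_h, p_n = spikein_expected_proportions(design, mass, pulldown)
                total = design.total_reads
                r_h = int(rng.binomial(total, p_h))
                r_n = int(rng.binomial(total, p_n))
                rows.append(
                    {
                        "library_id": f"{group}_{mass:g}ng_r{rep+1}",
                        "group": group,
                        "input_mass_ng": mass,
                        "spike_mass_fg": design.spike_mass_fg,
                        "reads_5hmc_probe": r_h,
                        "reads_no5hmc_probe": r_n,
                        "total_reads": total,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures


def write_fixtures(
    cohort: CountMatrix,
    catalog: FeatureCatalog,
    out_dir: str | Path,
    fragment_length: int = 150,
    mapq: int = 30,
) -> dict[str, Path]:
    """Write per-sample BED fragment files plus counts and metadata TSVs.

    Fragments are placed fully inside the gene body they count toward,
    so re-counting the BED files over the catalog's ``gene_bodies``
    category reproduces the count matrix exactly.
    """
    if cohort.counts.empty:
        raise ValueError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = {g.id: g for g in catalog.intervals("gene_bodies")}
    missing = set(cohort.feature_ids) - set(genes)
    if missing:
        raise ValueError(f"features absent from catalog gene bodies: {sorted(missing)[:5]}")

    paths: dict[str, Path] = {}
    frag_dir = out_dir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sid in cohort.sample_ids:
        path = frag_dir / f"{sid}.bed"
        with open(path, "w") as fh:
            for fid, count in cohort.counts[sid].items():
                g = genes[fid]
                flen = min(fragment_length, g.length)
                span = g.length - flen
                for k in range(int(count)):
                    # deterministic placement, cycling through the body
                    off = (k * 37) % (span + 1)
                    fh.write(
                        f"{g.chrom}\t{g.start + off}\t{g.start + off + flen}"
                        f"\t{sid}_f{k}\t{mapq}\t.\n"
                    )
        paths[sid] = path
    counts_path = out_dir / "counts.tsv"
    cohort.counts.rename_axis("feature_id").to_csv(counts_path, sep="\t")
    meta_path = out_dir / "metadata.tsv"
    cohort.metadata.rename_axis("sample_id").reset_index()[list(METADATA_COLUMNS)].to_csv(
        meta_path, sep="\t", index=False
    )
    paths["counts"] = counts_path
    paths["metadata"] = meta_path
    return paths


def read_fragments_bed(path: str | Path, sample_id: str | None = None) -> list[Fragment]:
    """Read a BED6 fragment file (score column carries MAPQ)."""
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    frags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            mapq = int(f[4]) if len(f) > 4 else 60
            frags.append(Fragment(f[0], int(f[1]), int(f[2]), mapq, sid))
    return frags
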