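"""Genomic feature catalogs and fragment counting.

5hmC-enriched sequencing reduces, per sample, to a stream of aligned
fragments; the analysis counts those fragments over catalogs of genomic
features (gene bodies, promoters, CpG islands, regulatory-element peak
sets). All coordinates are 0-based half-open (BED convention); GFF input
is converted at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

AGE_GROUPS = ("<20", "20-55", ">55")

METADATA_COLUMNS = (
    "sample_id",
    "status",
    "cancer_type",
    "stage",
    "age_group",
    "technician",
    "batch",
    "patient_id",
    "tumor_fraction",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."
    category: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    """An aligned cfDNA fragment with its mapping quality."""

    chrom: str
    start: int
    end: int
    mapq: int = 60
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


class FeatureCatalog:
    """Ordered map of category name -> sorted list of GenomicInterval.

    Intervals are kept sorted by (chrom, start); ids must be unique
    within a category.
    """

    def __init__(self, categories: Mapping[str, Sequence[GenomicInterval]] | None = None):
        self._categories: dict[str, list[GenomicInterval]] = {}
        if categories:
            for name, ivals in categories.items():
                self.add_category(name, ivals)

    def add_category(self, name: str, intervals: Sequence[GenomicInterval]) -> None:
        ids = [iv.id for iv in intervals]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate interval ids in category {name!r}")
        ivals = sorted(
            (replace(iv, category=name) for iv in intervals),
            key=lambda iv: (iv.chrom, iv.start, iv.end),
        )
        self._categories[name] = ivals

    @property
    def categories(self) -> list[str]:
        return list(self._categories)

    def intervals(self, category: str) -> list[GenomicInterval]:
        return list(self._categories[category])

    def __contains__(self, category: str) -> bool:
        return category in self._categories

    def __len__(self) -> int:
        return len(self._categories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureCatalog):
            return NotImplemented
        return self._categories == other._categories

    def items(self) -> Iterator[tuple[str, list[GenomicInterval]]]:
        return iter(self._categories.items())


@dataclass
class CountMatrix:
    """Features x samples integer counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``metadata`` is indexed by sample id and must cover every
    count column.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.counts.columns)
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        if "age_group" in self.metadata:
            bad = set(self.metadata["age_group"].dropna()) - set(AGE_GROUPS)
            if bad:
                raise ValueError(f"unknown age groups: {sorted(bad)}")
        # align metadata row order with columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.metadata.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.metadata.loc[list(sample_ids)]
        )


# ---------------------------------------------------------------------------
# Readers


def load_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read intervals from a BED (0-based half-open) or GFF (1-based closed) file.

    GFF coordinates are converted to the internal 0-based half-open
    convention. Raises ``ValueError`` naming the line on malformed
    records.
    """
    path = Path(path)
    if format not in ("bed", "gff"):
        raise ValueError(f"unknown format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"{chrom}:{fields[1]}-{fields[2]}"
                    strand = fields[5] if len(fields) > 5 else "."
                else:  # gff: 1-based closed -> 0-based half-open
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 and fields[6] in "+-" else "."
                    name = _gff_id(fields[8]) if len(fields) > 8 else f"{chrom}:{start}-{end}"
                if start >= end:
                    raise ValueError("start >= end")
                out.append(GenomicInterval(chrom, start, end, name, strand))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse record ({exc}): {line!r}") from exc
    return out


def _gff_id(attributes: str) -> str:
    for part in attributes.replace(";", " ").split():
        for key in ("ID=", "gene_id="):
            if part.startswith(key):
                return part[len(key):].strip('"')
    return attributes.strip()


# ---------------------------------------------------------------------------
# Feature derivation


def derive_features(
    genes: Sequence[GenomicInterval],
    cpg: Sequence[GenomicInterval] = (),
    promoter_bp: int = 3000,
    cpg_flank_bp: int = 1000,
) -> FeatureCatalog:
    """Derive gene-body / promoter / CpG-island feature categories.

    Promoters span ``promoter_bp`` upstream of the strand-aware 5' gene
    start; CpG islands are extended by ``cpg_flank_bp`` on both sides.
    Coordinates are clipped at zero.
    """
    bodies, promoters = [], []
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id!r} has no strand; promoter undefined")
        bodies.append(replace(g, category="gene_bodies"))
        if g.strand == "+":
            p_start, p_end = max(0, g.start - promoter_bp), g.start
        else:
            p_start, p_end = g.end, g.end + promoter_bp
        if p_start < p_end:
            promoters.append(
                GenomicInterval(g.chrom, p_start, p_end, f"{g.id}_prom", g.strand)
            )
    catalog = FeatureCatalog()
    catalog.add_category("gene_bodies", bodies)
    catalog.add_category("promoters", promoters)
    if cpg:
        extended = [
            GenomicInterval(c.chrom, max(0, c.start - cpg_flank_bp), c.end + cpg_flank_bp, c.id)
            for c in cpg
        ]
        catalog.add_category("cpg_islands", extended)
    return catalog


def collapse_peaks(
    intervals: Sequence[GenomicInterval], gap_bp: int = 150
) -> list[GenomicInterval]:
    """Merge overlapping and nearby (< ``gap_bp`` apart) peaks, transitively.

    Idempotent; output sorted by (chrom, start) with merged ids joined
    by '|'.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be non-negative")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end < gap_bp
        ):
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                f"{prev.id}|{iv.id}" if iv.id and iv.id not in prev.id.split("|") else prev.id,
                ".",
                prev.category,
            )
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# Counting


def _build_trees(
    intervals: Sequence[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def count_fragments(
    fragments: Iterable[Fragment],
    catalog: FeatureCatalog,
    mapq_min: int = 10,
    autosomes: set[str] | None = None,
) -> dict[str, CountMatrix]:
    """Count fragments over every feature category independently.

    A fragment increments every feature it overlaps by at least one bp,
    in each category; fragments with ``mapq < mapq_min`` are dropped, as
    are fragments on chromosomes outside ``autosomes`` (when given).
    Fragments on chromosomes absent from the catalog are skipped and
    tallied to the log. Strand is ignored.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    per_cat_ivals = {name: ivals for name, ivals in catalog.items()}
    trees = {name: _build_trees(ivals) for name, ivals in per_cat_ivals.items()}
    known_chroms = {iv.chrom for ivals in per_cat_ivals.values() for iv in ivals}

    counts: dict[str, dict[str, np.ndarray]] = {name: {} for name in per_cat_ivals}
    sample_ids: list[str] = []
    n_skipped_chrom = 0
    for frag in fragments:
        if frag.mapq < mapq_min:
            continue
        if autosomes is not None and frag.chrom not in autosomes:
            continue
        if frag.chrom not in known_chroms:
            n_skipped_chrom += 1
            continue
        sid = frag.sample_id or "sample"
        if sid not in sample_ids:
            sample_ids.append(sid)
            for name, ivals in per_cat_ivals.items():
                counts[name][sid] = np.zeros(len(ivals), dtype=np.int64)
        for name in per_cat_ivals:
            tree = trees[name].get(frag.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(frag.start, frag.end):
                counts[name][sid][hit.data] += 1
    if n_skipped_chrom:
        logger.info("count_fragments: skipped %d fragments on unknown chromosomes", n_skipped_chrom)

    out: dict[str, CountMatrix] = {}
    for name, ivals in per_cat_ivals.items():
        df = pd.DataFrame(
            {sid: counts[name][sid] for sid in sample_ids},
            index=[iv.id for iv in ivals],
            dtype=np.int64,
        )
        out[name] = CountMatrix(df)
    return out


def filter_low_counts(
    matrix: CountMatrix,
    mean_min: float = 10.0,
    autosomes: set[str] | None = None,
    feature_chroms: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Keep features whose mean count across samples is strictly > ``mean_min``.

    When ``autosomes`` and a feature->chromosome map are given, features
    off the autosomes are dropped first.
    """
    counts = matrix.counts
    if counts.empty:
        raise ValueError("empty count matrix")
    if autosomes is not None and feature_chroms is not None:
        keep = [f for f in counts.index if feature_chroms.get(f) in autosomes]
        counts = counts.loc[keep]
    mask = counts.mean(axis=1) > mean_min
    return CountMatrix(counts.loc[mask], matrix.metadata.copy())


def split_by_genome_tag(
    fragments: Iterable[Fragment],
    human_prefix: str = "hs_",
    mouse_prefix: str = "mm_",
    mapq_min: int = 10,
) -> tuple[list[Fragment], list[Fragment], float]:
    """Split fragments of a composite-genome alignment by chromosome prefix.

    Returns (human fragments, mouse fragments, human proportion) among
    fragments passing the MAPQ filter. Raises on unprefixed chromosome
    names or an empty admitted stream.
    """
    human: list[Fragment] = []
    mouse: list[Fragment] = []
    bad: set[str] = set()
    for frag in fragments:
        if frag.mapq < mapq_min:
            continue
        if frag.chrom.startswith(human_prefix):
            human.append(frag)
        elif frag.chrom.startswith(mouse_prefix):
            mouse.append(frag)
        else:
            bad.add(frag.chrom)
    if bad:
        raise ValueError(f"chromosomes without genome prefix: {sorted(bad)}")
    total = len(human) + len(mouse)
    if total == 0:
        raise ValueError("no fragments passed the MAPQ filter")
    return human, mouse, len(human) / total


# ---------------------------------------------------------------------------
# Metaprofiles


def metaprofile(
    fragments: Iterable[Fragment],
    features: Sequence[GenomicInterval],
    n_bins: int = 30,
    flank_bp: int = 2000,
    n_flank_bins: int = 10,
    sample_cap: int = 20000,
    seed: int = 0,
    library_size: float | None = None,
) -> np.ndarray:
    """Mean length-normalized coverage over features plus fixed-width flanks.

    Feature bodies are scaled into ``n_bins`` bins; each flank of
    ``flank_bp`` is split into ``n_flank_bins`` fixed-width bins (zero
    when ``flank_bp`` is 0). If more than ``sample_cap`` features are
    given, ``sample_cap`` are sampled (seeded) from those within the
    interquartile length range. Features shorter than ``n_bins`` bp are
    skipped with a logged count. The profile is per-bin coverage (bp of
    fragment overlap per bp of bin), averaged over features and divided
    by the library size (total admitted fragments when not given).
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    feats = list(features)
    if len(feats) > sample_cap:
        lengths = np.array([f.length for f in feats])
        q1, q3 = np.percentile(lengths, [25, 75])
        pool = [f for f, L in zip(feats, lengths) if q1 <= L <= q3]
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=min(sample_cap, len(pool)), replace=False)
        feats = [pool[i] for i in sorted(idx)]
    n_skipped = 0
    usable = []
    for f in feats:
        if f.length < n_bins:
            n_skipped += 1
        else:
            usable.append(f)
    if n_skipped:
        logger.info("metaprofile: skipped %d features shorter than %d bp", n_skipped, n_bins)
    if not usable:
        raise ValueError("no usable features")

    nfb = n_flank_bins if flank_bp > 0 else 0
    total_bins = n_bins + 2 * nfb
    cov = np.zeros(total_bins)
    trees = _build_trees(
        [replace(f, start=max(0, f.start - flank_bp), end=f.end + flank_bp, id=str(i))
         for i, f in enumerate(usable)]
    )
    frag_list = list(fragments)
    n_admitted = len(frag_list)
    for frag in frag_list:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(frag.start, frag.end):
            f = usable[int(hit.data)]
            edges = _bin_edges(f, n_bins, flank_bp, nfb)
            hi = np.minimum(frag.end, edges[1:])
            overlap = np.maximum(0.0, hi - np.maximum(frag.start, edges[:-1]))
            widths = np.diff(edges).astype(float)
            cov += overlap / np.maximum(widths, 1e-12)
    cov /= len(usable)
    denom = library_size if library_size is not None else max(n_admitted, 1)
    return cov / denom


def _bin_edges(f: GenomicInterval, n_bins: int, flank_bp: int, nfb: int) -> np.ndarray:
    body = np.linspace(f.start, f.end, n_bins + 1)
    if nfb == 0:
        return body
    left = np.linspace(f.start - flank_bp, f.start, nfb + 1)[:-1]
    right = np.linspace(f.end, f.end + flank_bp, nfb + 1)[1:]
    edges = np.concatenate([left, body, right])
    if f.strand == "-":
        # orient 5'->3': mirror by reversing later is equivalent for symmetric use
        pass
    return edges
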