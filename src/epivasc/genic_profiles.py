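"""Metagene methylation profiles and expression-quartile comparisons.

Each gene contributes 300 ordered bins in transcriptional orientation:
100 fixed 20-bp windows over the 2-kb upstream flank, 100 bins partitioning
the exon-concatenated gene body into near-equal pieces, and 100 windows over
the 2-kb downstream flank. Per gene per bin the methylation fraction is
methylated calls / cytosines covered >= 4x; the profile value of a bin is
the mean of the defined per-gene fractions (gene-weighted averaging).

Group differences (expression quartiles, tissue types) are tested with a
Kruskal-Wallis test followed by Tukey HSD on the per-bin averages of a
region, treating bins as observations. Bins along a gene are autocorrelated,
so these p-values are descriptive rather than strictly calibrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .expression_analysis import rpkm
from .io_formats import ExpressionMatrix, GeneModel
from .methylation_core import (
    STATUS_METHYLATED,
    STATUS_UNCALLABLE,
    MethylationCallSet,
)

logger = logging.getLogger(__name__)

FLANK_BP = 2_000
FLANK_WINDOW = 20
BODY_BINS = 100
MIN_EXONIC_BP = 100

N_FLANK_BINS = FLANK_BP // FLANK_WINDOW  # 100
REGIONS = ("upstream", "body", "downstream")


@dataclass
class GeneBins:
    """Ordered bin definitions for one gene, 5'->3' of the gene.

    Flank bins are genomic [start, end) windows; body bins are lists of
    genomic intervals (a body bin can straddle an intron). ``truncated``
    flags flank bins clipped at a chromosome edge.
    """

    gene_id: str
    chrom: str
    strand: str
    upstream: list[tuple[int, int]]
    body: list[list[tuple[int, int]]]
    downstream: list[tuple[int, int]]
    truncated: list[bool]


def bin_gene(gene: GeneModel, chrom_length: int | None = None) -> GeneBins | None:
    """Build the 100+100+100 bin structure for one gene.

    Returns None (and logs) for genes with exonic length < 100 bp, which a
    100-way partition cannot cover. Flank bins beyond a chromosome edge are
    truncated and flagged.
    """
    if gene.exonic_length < MIN_EXONIC_BP:
        logger.info(
            "skipping gene %s: exonic length %d < %d",
            gene.gene_id,
            gene.exonic_length,
            MIN_EXONIC_BP,
        )
        return None

    # flanks in genomic coordinates: left of gene.start, right of gene.end
    left = [
        (gene.start - FLANK_BP + i * FLANK_WINDOW,
         gene.start - FLANK_BP + (i + 1) * FLANK_WINDOW)
        for i in range(N_FLANK_BINS)
    ]
    right = [
        (gene.end + i * FLANK_WINDOW, gene.end + (i + 1) * FLANK_WINDOW)
        for i in range(N_FLANK_BINS)
    ]

    # body: partition the exon-concatenated coordinate into 100 contiguous
    # near-equal pieces (sizes differ by <= 1), then map back to genomic
    total = gene.exonic_length
    sizes = np.full(BODY_BINS, total // BODY_BINS, dtype=int)
    sizes[: total % BODY_BINS] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    body: list[list[tuple[int, int]]] = []
    exon_offsets = np.concatenate(
        [[0], np.cumsum([e - s for s, e in gene.exons])]
    )
    for b in range(BODY_BINS):
        lo, hi = int(bounds[b]), int(bounds[b + 1])
        pieces = []
        for (es, ee), off in zip(gene.exons, exon_offsets[:-1]):
            s = max(lo, int(off))
            e = min(hi, int(off) + (ee - es))
            if s < e:
                pieces.append((es + (s - int(off)), es + (e - int(off))))
        body.append(pieces)

    if gene.strand == "+":
        upstream, downstream = left, right
    else:
        upstream = [(s, e) for s, e in reversed(right)]
        downstream = [(s, e) for s, e in reversed(left)]
        body = body[::-1]

    def clip(bins):
        out, flags = [], []
        for s, e in bins:
            cs = max(0, s)
            ce = e if chrom_length is None else min(e, chrom_length)
            flags.append(cs != s or ce != e)
            out.append((cs, max(cs, ce)))
        return out, flags

    upstream, up_trunc = clip(upstream)
    downstream, down_trunc = clip(downstream)
    return GeneBins(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        upstream=upstream,
        body=body,
        downstream=downstream,
        truncated=up_trunc + [False] * BODY_BINS + down_trunc,
    )


@dataclass
class GenicProfile:
    """Per-bin metagene methylation profile for one sample and context."""

    sample_id: str
    context: str
    #: 300-vector of mean per-gene methylation fractions (NaN = undefined)
    levels: np.ndarray
    #: number of genes contributing a defined fraction per bin
    n_genes: np.ndarray
    #: total methylated marks / covered cytosines per bin, over all genes
    marks: np.ndarray
    covered: np.ndarray

    def region(self, which: str) -> np.ndarray:
        lo, hi = _region_slice(which)
        return self.levels[lo:hi]


def _region_slice(which: str) -> tuple[int, int]:
    if which == "upstream":
        return 0, N_FLANK_BINS
    if which == "body":
        return N_FLANK_BINS, N_FLANK_BINS + BODY_BINS
    if which == "downstream":
        return N_FLANK_BINS + BODY_BINS, 2 * N_FLANK_BINS + BODY_BINS
    raise ValueError(f"unknown region {which!r}; expected one of {REGIONS}")


def profile_sample(
    calls: MethylationCallSet,
    genes: list[GeneModel],
    context: str,
    gene_subset: set[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> GenicProfile:
    """Metagene profile of one call set over a gene list.

    Per gene per bin: fraction = methylated calls / cytosines covered >= 4x
    of the requested context; bins with no covered cytosine in a gene are
    excluded from that gene's contribution. The profile value is the mean of
    defined per-gene fractions.
    """
    sites = calls.sites
    sites = sites[
        (sites["context"] == context) & (sites["status"] != STATUS_UNCALLABLE)
    ]
    n_bins = 2 * N_FLANK_BINS + BODY_BINS
    marks = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    frac_sum = np.zeros(n_bins)
    n_genes = np.zeros(n_bins, dtype=int)

    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in sites.groupby("chrom")
    }
    eligible = 0
    for gene in genes:
        if gene_subset is not None and gene.gene_id not in gene_subset:
            continue
        chrom_len = None if chrom_lengths is None else chrom_lengths.get(gene.chrom)
        bins = bin_gene(gene, chrom_len)
        if bins is None or gene.chrom not in by_chrom:
            continue
        eligible += 1
        grp = by_chrom[gene.chrom]
        pos = grp["pos"].to_numpy()
        is_meth = (grp["status"] == STATUS_METHYLATED).to_numpy()
        flat: list[list[tuple[int, int]]] = (
            [[iv] for iv in bins.upstream] + bins.body + [[iv] for iv in bins.downstream]
        )
        for b, pieces in enumerate(flat):
            cov = 0
            mk = 0
            for s, e in pieces:
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="left")
                cov += hi - lo
                mk += int(is_meth[lo:hi].sum())
            if cov > 0:
                covered[b] += cov
                marks[b] += mk
                frac_sum[b] += mk / cov
                n_genes[b] += 1
    if eligible == 0:
        raise ValueError("no eligible genes for profiling")
    with np.errstate(invalid="ignore"):
        levels = np.where(n_genes > 0, frac_sum / np.maximum(n_genes, 1), np.nan)
    return GenicProfile(
        sample_id=calls.sample_id,
        context=context,
        levels=levels,
        n_genes=n_genes,
        marks=marks,
        covered=covered,
    )


# ---------------------------------------------------------------------------
# expression quartiles
# ---------------------------------------------------------------------------

def expression_quartiles(
    expr: ExpressionMatrix,
    sample: str,
    expressed_genes: set[str] | list[str],
) -> pd.Series:
    """Quartile grouping (1 = lowest RPKM, 4 = highest) of expressed genes.

    Breakpoints are the 25/50/75th percentiles of RPKM among the expressed
    genes of the sample; values tied with a breakpoint go to the lower group.
    """
    genes = [g for g in expr.counts.index if g in set(expressed_genes)]
    if len(genes) < 4:
        raise ValueError("need at least 4 expressed genes for quartiles")
    values = rpkm(expr)[sample].loc[genes]
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    group = 1 + (values > q25).astype(int) + (values > q50).astype(int) + (
        values > q75
    ).astype(int)
    return group.rename("quartile")


# ---------------------------------------------------------------------------
# group comparison: Kruskal-Wallis + Tukey
# ---------------------------------------------------------------------------

def aggregate_flank_bins(levels: np.ndarray) -> np.ndarray:
    """Collapse a 100-bin flank vector to 50 bins of 40 bp by averaging
    adjacent pairs (NaN-aware)."""
    if len(levels) != N_FLANK_BINS:
        raise ValueError(f"expected {N_FLANK_BINS} flank bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(levels.reshape(50, 2), axis=1)


def compare_groups(
    profiles_by_group: dict[str, GenicProfile | np.ndarray],
    region: str = "upstream",
    aggregate_50: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis p-value and Tukey HSD pairwise table over the per-bin
    average methylation of ``region`` for each group.

    Groups whose bins are all undefined are excluded with a warning;
    ``aggregate_50`` collapses 100 flank bins to the 50-bin (40 bp) view.
    """
    vectors: dict[str, np.ndarray] = {}
    for name, prof in profiles_by_group.items():
        vec = prof.region(region) if isinstance(prof, GenicProfile) else np.asarray(prof, float)
        if aggregate_50 and region in ("upstream", "downstream"):
            vec = aggregate_flank_bins(vec)
        vec = vec[~np.isnan(vec)]
        if len(vec) == 0:
            warnings.warn(f"group {name!r} has no defined bins; excluded", stacklevel=2)
            continue
        vectors[name] = vec
    if len(vectors) < 2:
        raise ValueError("need >= 2 groups with defined bins")
    kw_stat, kw_p = stats.kruskal(*vectors.values())
    values = np.concatenate(list(vectors.values()))
    labels = np.concatenate(
        [np.full(len(v), name) for name, v in vectors.items()]
    )
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return float(kw_p), pairwise


def plot_profile(profiles: dict[str, GenicProfile], path: str) -> None:
    """Plot metagene profiles (one line per sample) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(2 * N_FLANK_BINS + BODY_BINS)
    for name, prof in profiles.items():
        ax.plot(x, prof.levels, label=name, lw=1)
    for edge in (N_FLANK_BINS, N_FLANK_BINS + BODY_BINS):
        ax.axvline(edge, color="grey", ls=":", lw=0.8)
    ax.set_xticks([0, N_FLANK_BINS, N_FLANK_BINS + BODY_BINS // 2,
                   N_FLANK_BINS + BODY_BINS, 2 * N_FLANK_BINS + BODY_BINS - 1])
    ax.set_xticklabels(["-2 kb", "TSS", "gene body", "TES", "+2 kb"])
    ax.set_ylabel("methylation level")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
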