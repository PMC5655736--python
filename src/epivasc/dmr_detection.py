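"""Sliding-window DMR detection, gene association, hypermethylated-gene
calling and DMR clustering.

DMRs between two (replicate-pooled) samples are found with 100-bp windows
stepped by 50 bp. Only cytosines covered >= 4x in *both* samples count; a
window is tested only when it holds >= 15 such cytosines, all three contexts
pooled. Each tested window gets a two-sided Fisher exact p-value on the
read-level 2x2 table (methylated vs unmethylated reads, sample A vs B).
Touching/overlapping windows with p < 0.001 are concatenated, and a merged
region is a DMR when its weighted methylation level is < 30% in one sample
and > 70% in the other. DMRs associate with any gene whose span extended by
1 kb on each side they intersect.

Per-gene hypermethylation against the genome-wide background uses a
one-tailed binomial test on the gene's methylated-cytosine count (N >= 20
cytosines required), BH-corrected at FDR <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, GenomeSequence
from .methylation_core import (
    MIN_COVERAGE,
    STATUS_METHYLATED,
    STATUS_UNCALLABLE,
    MethylationCallSet,
    binomial_tail,
)

WINDOW_SIZE = 100
WINDOW_STEP = 50
MIN_CYTOSINES = 15
WINDOW_ALPHA = 0.001
LOW_CUT = 0.30
HIGH_CUT = 0.70
GENE_FLANK = 1_000
HYPER_MIN_CYTOSINES = 20
HYPER_FDR = 0.05


@dataclass
class MethWindow:
    chrom: str
    start: int
    end: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    n_cytosines: int
    tested: bool
    p_value: float = float("nan")


@dataclass
class DmrRecord:
    chrom: str
    start: int
    end: int
    level_a: float
    level_b: float
    direction: str  # sample id that is hypermethylated
    p_value: float  # minimum window p in the merged region
    name: str = ""
    associated_genes: list[tuple[str, str]] = field(default_factory=list)


def _joint_site_table(
    calls_a: MethylationCallSet, calls_b: MethylationCallSet, min_cov: int
) -> pd.DataFrame:
    a = calls_a.sites[["chrom", "pos", "meth", "total"]]
    b = calls_b.sites[["chrom", "pos", "meth", "total"]]
    a = a[a["total"] >= min_cov]
    b = b[b["total"] >= min_cov]
    joint = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    return joint


def build_windows(
    calls_a: MethylationCallSet,
    calls_b: MethylationCallSet,
    genome: GenomeSequence | dict[str, int],
    window_size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    min_cytosines: int = MIN_CYTOSINES,
    min_cov: int = MIN_COVERAGE,
    context: str | None = None,
) -> list[MethWindow]:
    """Tile each chromosome with fixed windows and accumulate read counts.

    Windows start at 0 and step by ``step``; only windows fully inside the
    chromosome are kept. A cytosine contributes only if covered >= ``min_cov``
    in both samples (both strands kept separate). ``context`` optionally
    restricts to one context; the default pools CG+CHG+CHH.
    """
    lengths = (
        {c: genome.length(c) for c in genome.chrom_names}
        if isinstance(genome, GenomeSequence)
        else dict(genome)
    )
    sites_a = calls_a.sites
    if context is not None:
        sites_a = sites_a[sites_a["context"] == context]
        calls_b_sites = calls_b.sites[calls_b.sites["context"] == context]
    else:
        calls_b_sites = calls_b.sites
    joint = _joint_site_table(
        MethylationCallSet(calls_a.sample_id, sites_a, calls_a.error_rate),
        MethylationCallSet(calls_b.sample_id, calls_b_sites, calls_b.error_rate),
        min_cov,
    )

    windows: list[MethWindow] = []
    for chrom, grp in joint.groupby("chrom", sort=True):
        chrom_len = lengths.get(chrom)
        if chrom_len is None:
            continue
        pos = grp["pos"].to_numpy()
        cols = {
            c: grp[c].to_numpy()
            for c in ("meth_a", "total_a", "meth_b", "total_b")
        }
        n_windows = (chrom_len - window_size) // step + 1 if chrom_len >= window_size else 0
        # each site falls in up to window_size//step windows
        counts = np.zeros((n_windows, 5), dtype=np.int64)
        for offset in range(0, window_size, step):
            w = (pos - offset) // window_size
            inside = (pos - offset >= 0) & (w * window_size + offset + window_size <= chrom_len)
            widx = (w[inside] * window_size + offset) // step
            valid = widx < n_windows
            widx = widx[valid]
            sel = np.flatnonzero(inside)[valid]
            np.add.at(counts[:, 0], widx, cols["meth_a"][sel])
            np.add.at(counts[:, 1], widx, cols["total_a"][sel] - cols["meth_a"][sel])
            np.add.at(counts[:, 2], widx, cols["meth_b"][sel])
            np.add.at(counts[:, 3], widx, cols["total_b"][sel] - cols["meth_b"][sel])
            np.add.at(counts[:, 4], widx, 1)
        for i in range(n_windows):
            start = i * step
            ma, ua, mb, ub, nc = counts[i]
            tested = nc >= min_cytosines and (ma + ua + mb + ub) > 0
            windows.append(
                MethWindow(
                    chrom=chrom,
                    start=int(start),
                    end=int(start + window_size),
                    meth_a=int(ma),
                    unmeth_a=int(ua),
                    meth_b=int(mb),
                    unmeth_b=int(ub),
                    n_cytosines=int(nc),
                    tested=bool(tested),
                )
            )
    return windows


def window_fisher(window: MethWindow) -> float:
    """Two-sided Fisher exact p on [meth, unmeth] x [sample A, sample B]."""
    if not window.tested:
        raise ValueError("window is not eligible for testing")
    table = [
        [window.meth_a, window.unmeth_a],
        [window.meth_b, window.unmeth_b],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def score_windows(windows: list[MethWindow]) -> list[MethWindow]:
    """Fill p-values of all tested-eligible windows in place."""
    for w in windows:
        if w.tested:
            w.p_value = window_fisher(w)
    return windows


def merge_windows(
    windows: list[MethWindow], alpha: float = WINDOW_ALPHA
) -> list[tuple[str, int, int, float]]:
    """Concatenate touching/overlapping significant (p < alpha, strict)
    windows into maximal regions. Returns (chrom, start, end, min_p) tuples,
    disjoint and sorted."""
    sig = sorted(
        (w for w in windows if w.tested and w.p_value < alpha),
        key=lambda w: (w.chrom, w.start),
    )
    regions: list[tuple[str, int, int, float]] = []
    for w in sig:
        if regions and regions[-1][0] == w.chrom and w.start <= regions[-1][2]:
            chrom, start, end, p = regions[-1]
            regions[-1] = (chrom, start, max(end, w.end), min(p, w.p_value))
        else:
            regions.append((w.chrom, w.start, w.end, w.p_value))
    return regions


def classify_dmrs(
    regions: list[tuple[str, int, int, float]],
    calls_a: MethylationCallSet,
    calls_b: MethylationCallSet,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
    min_cov: int = MIN_COVERAGE,
) -> list[DmrRecord]:
    """Apply the <30% / >70% weighted-level rule to candidate regions.

    Region levels are weighted methylation over the cytosines covered >= 4x
    in both samples; inequalities are strict.
    """
    joint = _joint_site_table(calls_a, calls_b, min_cov)
    dmrs: list[DmrRecord] = []
    for chrom, start, end, min_p in regions:
        sel = joint[
            (joint["chrom"] == chrom)
            & (joint["pos"] >= start)
            & (joint["pos"] < end)
        ]
        tot_a, tot_b = sel["total_a"].sum(), sel["total_b"].sum()
        if tot_a == 0 or tot_b == 0:
            continue
        level_a = float(sel["meth_a"].sum() / tot_a)
        level_b = float(sel["meth_b"].sum() / tot_b)
        lo, hi = min(level_a, level_b), max(level_a, level_b)
        if lo < low_cut and hi > high_cut:
            direction = (
                calls_a.sample_id if level_a > level_b else calls_b.sample_id
            )
            dmrs.append(
                DmrRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    level_a=level_a,
                    level_b=level_b,
                    direction=direction,
                    p_value=min_p,
                    name=f"DMR_{len(dmrs) + 1}",
                )
            )
    return dmrs


def associate_genes(
    dmrs: list[DmrRecord], genes: list[GeneModel], flank: int = GENE_FLANK
) -> list[DmrRecord]:
    """Associate each DMR with every gene whose span extended by ``flank``
    bp on both sides intersects it; the relation records where the DMR sits
    relative to the gene (overlap / 5' flank / 3' flank)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for dmr in dmrs:
        dmr.associated_genes = []
        for g in by_chrom.get(dmr.chrom, []):
            if dmr.start < g.end + flank and dmr.end > g.start - flank:
                if dmr.start < g.end and dmr.end > g.start:
                    relation = "overlap"
                elif dmr.end <= g.start:
                    relation = "5_prime" if g.strand == "+" else "3_prime"
                else:
                    relation = "3_prime" if g.strand == "+" else "5_prime"
                dmr.associated_genes.append((g.gene_id, relation))
    return dmrs


# ---------------------------------------------------------------------------
# per-gene hypermethylation
# ---------------------------------------------------------------------------

def hypermethylated_genes(
    calls: MethylationCallSet,
    genes: list[GeneModel],
    context: str,
    min_cytosines: int = HYPER_MIN_CYTOSINES,
    fdr: float = HYPER_FDR,
) -> pd.DataFrame:
    """One-tailed binomial hypermethylation test per gene.

    N = cytosines of ``context`` covered >= 4x within the gene span, K =
    those called methylated, and the background P is the genome-wide
    fraction of callable cytosines of that context called methylated in the
    same call set. Genes with N < ``min_cytosines`` are excluded; BH across
    tested genes; significant iff q <= ``fdr``.
    """
    sites = calls.sites
    sites = sites[
        (sites["context"] == context) & (sites["status"] != STATUS_UNCALLABLE)
    ]
    if len(sites) == 0:
        raise ValueError(f"no callable {context} sites")
    meth = (sites["status"] == STATUS_METHYLATED).to_numpy()
    p_bg = float(meth.mean())
    if p_bg in (0.0, 1.0):
        raise ValueError(
            f"degenerate genome-wide methylation background ({p_bg}) for {context}"
        )
    pos_by_chrom = {
        chrom: (grp["pos"].to_numpy(), (grp["status"] == STATUS_METHYLATED).to_numpy())
        for chrom, grp in sites.groupby("chrom")
    }
    rows = []
    for g in genes:
        if g.chrom not in pos_by_chrom:
            continue
        pos, is_meth = pos_by_chrom[g.chrom]
        lo = np.searchsorted(pos, g.start, side="left")
        hi = np.searchsorted(pos, g.end, side="left")
        n = int(hi - lo)
        if n < min_cytosines:
            continue
        k = int(is_meth[lo:hi].sum())
        rows.append(
            {
                "gene_id": g.gene_id,
                "context": context,
                "N": n,
                "K": k,
                "p_bg": p_bg,
                "p_value": binomial_tail(k, n, p_bg),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "context", "N", "K", "p_bg", "p_value", "q_value",
                     "significant"]
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = q
    out["significant"] = out["q_value"] <= fdr
    return out


# ---------------------------------------------------------------------------
# DMR clustering
# ---------------------------------------------------------------------------

def dmr_level_matrix(
    dmrs: list[DmrRecord], calls_by_sample: dict[str, MethylationCallSet],
    min_cov: int = MIN_COVERAGE,
) -> pd.DataFrame:
    """DMR x sample matrix of weighted methylation levels (NaN-free: DMRs
    with no covered cytosine in some sample are dropped)."""
    rows = {}
    for dmr in dmrs:
        levels = {}
        for sid, calls in calls_by_sample.items():
            sel = calls.sites[
                (calls.sites["chrom"] == dmr.chrom)
                & (calls.sites["pos"] >= dmr.start)
                & (calls.sites["pos"] < dmr.end)
                & (calls.sites["total"] >= min_cov)
            ]
            tot = sel["total"].sum()
            levels[sid] = float(sel["meth"].sum() / tot) if tot > 0 else np.nan
        rows[dmr.name or f"{dmr.chrom}:{dmr.start}-{dmr.end}"] = levels
    mat = pd.DataFrame(rows).T
    return mat.dropna()


def cluster_dmrs(
    level_matrix: pd.DataFrame, k: int = 4, seed: int = 0
) -> tuple[pd.Series, float]:
    """K-means clustering of DMRs on their per-sample methylation levels.

    Returns (labels indexed by DMR, silhouette score). The silhouette is NaN
    for k=1 or degenerate (all-identical) inputs, which are signalled with a
    warning.
    """
    if k > len(level_matrix):
        raise ValueError(f"k={k} exceeds the number of DMRs ({len(level_matrix)})")
    x = level_matrix.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(x)
    sil = float("nan")
    if k >= 2:
        if len(np.unique(labels)) < 2 or np.allclose(x, x[0]):
            warnings.warn("degenerate clustering: identical feature vectors",
                          stacklevel=2)
        elif len(np.unique(labels)) < len(x):
            sil = float(silhouette_score(x, labels))
    return pd.Series(labels, index=level_matrix.index, name="cluster"), sil
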