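"""Synthetic genomes, methylomes and expression matrices with known truth.

The generator emulates the structure of a laser-capture tissue study:
4 sample classes (root, shoot, vascular, nonvascular) x 3 biological
replicates; per-context genome-wide methylation rates ordered CG > CHG > CHH;
site coverage around 4-12x; a fully unmethylated spike-in chromosome whose
apparent methylation estimates the bisulfite non-conversion (error) rate,
drawn inside the 0.01-0.33% range; planted DMRs between two tissue classes;
negative-binomial expression counts with planted DE genes and a coexpression
module around a reference gene.

The simulation is site-level, not read-level: each cytosine carries a true
binary methylation state, and observed methylated read counts are binomial
given Poisson coverage. Methylated sites emit reads at 1 - error_rate,
unmethylated sites at error_rate (the single spike-in-derived rate applied
symmetrically). Replicates differ only by sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    METHCOUNTS_COLUMNS,
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
)

DEFAULT_TISSUES = ("root", "shoot", "vascular", "nonvascular")

SPIKEIN_CHROM = "spikein"


@dataclass
class PlantedDmr:
    chrom: str
    start: int
    end: int
    tissue_high: str
    rate_high: float = 0.9
    rate_low: float = 0.05

    def __post_init__(self) -> None:
        if not (self.rate_high > 0.7 and self.rate_low < 0.3):
            raise ValueError(
                "planted DMR rates must straddle the 30%/70% rule "
                f"(got high={self.rate_high}, low={self.rate_low})"
            )


@dataclass
class MethylomeTruth:
    """Ground truth for a simulated methylome.

    Baseline per-context rates are the probability that a cytosine of that
    context is truly methylated; defaults follow the CG > CHG > CHH ordering
    of a heavily methylated C4 grass genome (mCG ~0.85, mCHG ~0.65,
    mCHH ~0.05).
    """

    rate_cg: float = 0.85
    rate_chg: float = 0.65
    rate_chh: float = 0.05
    gene_body_cg_multiplier: float = 1.0
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    error_rate: float = 0.002
    coverage_mean: float = 8.0
    #: fraction of sites whose true state is re-drawn independently per
    #: tissue (models tissue-of-origin epigenetic divergence)
    state_divergence: float = 0.0

    def __post_init__(self) -> None:
        # 0.0 is allowed as a degenerate no-error world; anything else must
        # sit inside the spike-in-estimated range
        if self.error_rate != 0.0 and not 0.0001 <= self.error_rate <= 0.0033:
            raise ValueError(
                "error_rate outside the spike-in-estimated range [0.0001, 0.0033]"
            )
        _check_disjoint(self.planted_dmrs)


def _check_disjoint(dmrs: list[PlantedDmr]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping planted DMRs on {chrom}")


@dataclass
class ExpressionTruth:
    """Ground truth for a simulated expression matrix."""

    #: (gene_id, tissue_up, log2 fold change > 0)
    planted_de: list[tuple[str, str, float]] = field(default_factory=list)
    #: (reference_gene_id, member_gene_ids, target Pearson correlation)
    coexpression_module: tuple[str, list[str], float] | None = None
    dispersion: float = 0.05
    baseline_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for gene, _, lfc in self.planted_de:
            if lfc <= 0:
                raise ValueError(f"planted fold change for {gene} must be > 1")


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int,
    chrom_length: int,
    gc_fraction: float = 0.44,
    seed: int = 0,
    spikein_length: int = 20_000,
) -> GenomeSequence:
    """Generate i.i.d. random chromosomes plus an unmethylated ``spikein``
    control chromosome at the same base composition."""
    if not 0 < gc_fraction < 1:
        raise ValueError(f"gc_fraction must be in (0,1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    alphabet = np.array(list("ACGT"))
    names, seqs = [], {}
    for i in range(n_chrom):
        names.append(f"chr{i + 1}")
        seqs[names[-1]] = "".join(alphabet[rng.choice(4, size=chrom_length, p=p)])
    names.append(SPIKEIN_CHROM)
    seqs[SPIKEIN_CHROM] = "".join(alphabet[rng.choice(4, size=spikein_length, p=p)])
    return GenomeSequence(names, seqs)


def generate_gene_models(
    genome: GenomeSequence,
    n_genes: int,
    gene_length: int = 2_000,
    n_exons: int = 2,
    spacing: int = 6_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes along the non-spike-in
    chromosomes, alternating strand, leaving >= 2 kb flanks."""
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome.chrom_names if c != SPIKEIN_CHROM]
    genes: list[GeneModel] = []
    gid = 0
    for chrom in chroms:
        pos = 2_500
        while pos + gene_length + 2_500 <= genome.length(chrom) and gid < n_genes:
            start, end = pos, pos + gene_length
            if n_exons <= 1:
                exons = [(start, end)]
            else:
                # cut the span into exons separated by short fixed introns
                intron = min(200, (end - start) // (4 * n_exons))
                cuts = np.linspace(start, end, n_exons + 1).astype(int)
                exons = [
                    (int(cuts[i]) + (intron if i else 0), int(cuts[i + 1]))
                    for i in range(n_exons)
                ]
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
            pos += gene_length + spacing
    return genes


_COMP = str.maketrans("ACGTN", "TGCAN")


def annotate_contexts(genome: GenomeSequence) -> pd.DataFrame:
    """Catalogue every cytosine on both strands with its CG/CHG/CHH context.

    Context is read from the strand's own 5'->3' sequence (a minus-strand
    cytosine appears as G on the reference). Positions too close to a
    chromosome end for a full triplet fall back to the context determinable
    from the available bases (CHH if nothing disambiguates); triplets
    containing N are skipped.
    """
    frames = []
    for chrom in genome.chrom_names:
        seq = np.frombuffer(genome.sequences[chrom].encode(), dtype="S1")
        n = len(seq)
        for strand in "+-":
            if strand == "+":
                pos = np.flatnonzero(seq == b"C")
                nxt1 = _base_at(seq, pos + 1)
                nxt2 = _base_at(seq, pos + 2)
            else:
                pos = np.flatnonzero(seq == b"G")
                nxt1 = _complement(_base_at(seq, pos - 1))
                nxt2 = _complement(_base_at(seq, pos - 2))
            ctx = np.full(len(pos), "CHH", dtype="U3")
            ctx[nxt1 == b"G"] = "CG"
            ctx[(nxt1 != b"G") & (nxt1 != b"N") & (nxt2 == b"G")] = "CHG"
            keep = (nxt1 != b"N") & ((nxt1 == b"G") | (nxt2 != b"N"))
            # off-end lookups return b'.', meaning "no base": context falls
            # back to what the available bases determine
            off1 = nxt1 == b"."
            off2 = nxt2 == b"."
            keep |= off1 | (off2 & (nxt1 != b"N"))
            ctx[off1] = "CHH"
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": strand,
                        "context": ctx[keep],
                    }
                )
            )
        del n
    cat = pd.concat(frames, ignore_index=True)
    return cat.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def _base_at(seq: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Base at each index, or b'.' where the index falls off the sequence."""
    out = np.full(len(idx), b".", dtype="S1")
    ok = (idx >= 0) & (idx < len(seq))
    out[ok] = seq[idx[ok]]
    return out


def _complement(bases: np.ndarray) -> np.ndarray:
    table = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"N": b"N", b".": b"."}
    out = np.empty_like(bases)
    for k, v in table.items():
        out[bases == k] = v
    return out


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    genome: GenomeSequence,
    genes: list[GeneModel],
    truth: MethylomeTruth,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    n_replicates: int = 3,
    seed: int = 0,
    return_states: bool = False,
):
    """Simulate one methcounts table per (tissue, replicate).

    Returns a dict keyed by (tissue, replicate index starting at 1). Each
    table includes the spike-in chromosome's sites (all truly unmethylated).
    Sites that draw zero coverage in a replicate are omitted from that
    replicate's table, as they would be from real count output.

    With ``return_states=True`` also returns the per-tissue true binary
    methylation states as a DataFrame (chrom, pos, strand, context + one
    boolean column per tissue) for ground-truth assertions.
    """
    for d in truth.planted_dmrs:
        if d.chrom not in genome or d.end > genome.length(d.chrom):
            raise ValueError(f"planted DMR outside genome: {d.chrom}:{d.start}-{d.end}")
        if d.tissue_high not in tissues:
            raise ValueError(f"planted DMR tissue {d.tissue_high!r} not simulated")

    catalog = annotate_contexts(genome)
    rng = np.random.default_rng(seed)

    rate = np.select(
        [catalog["context"] == "CG", catalog["context"] == "CHG"],
        [truth.rate_cg, truth.rate_chg],
        default=truth.rate_chh,
    ).astype(float)

    if truth.gene_body_cg_multiplier != 1.0 and genes:
        exonic = _mask_intervals(
            catalog,
            [(g.chrom, s, e) for g in genes for s, e in g.exons],
        )
        cg = (catalog["context"] == "CG").to_numpy()
        rate[exonic & cg] = np.clip(
            rate[exonic & cg] * truth.gene_body_cg_multiplier, 0.0, 1.0
        )

    spike = (catalog["chrom"] == SPIKEIN_CHROM).to_numpy()
    rate[spike] = 0.0

    # shared genome-wide true states; tissues diverge only through planted
    # DMRs and the optional state_divergence re-draw
    base_state = rng.random(len(catalog)) < rate
    state_by_tissue: dict[str, np.ndarray] = {}
    for tissue in tissues:
        state = base_state.copy()
        if truth.state_divergence > 0:
            redraw = rng.random(len(catalog)) < truth.state_divergence
            redraw &= ~spike
            state[redraw] = rng.random(int(redraw.sum())) < rate[redraw]
        for d in truth.planted_dmrs:
            mask = (
                (catalog["chrom"] == d.chrom)
                & (catalog["pos"] >= d.start)
                & (catalog["pos"] < d.end)
            ).to_numpy()
            r = d.rate_high if tissue == d.tissue_high else d.rate_low
            state[mask] = rng.random(int(mask.sum())) < r
        state_by_tissue[tissue] = state

    err = truth.error_rate
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    for tissue in tissues:
        emit = np.where(state_by_tissue[tissue], 1.0 - err, err)
        for rep in range(1, n_replicates + 1):
            cov = rng.poisson(truth.coverage_mean, size=len(catalog))
            meth = rng.binomial(cov, emit)
            keep = cov > 0
            df = pd.DataFrame(
                {
                    "chrom": catalog["chrom"].to_numpy()[keep],
                    "pos": catalog["pos"].to_numpy()[keep],
                    "strand": catalog["strand"].to_numpy()[keep],
                    "context": catalog["context"].to_numpy()[keep],
                    "meth": meth[keep],
                    "total": cov[keep],
                }
            )[METHCOUNTS_COLUMNS]
            tables[(tissue, rep)] = df
    if return_states:
        states = catalog.copy()
        for tissue in tissues:
            states[tissue] = state_by_tissue[tissue]
        return tables, states
    return tables


def _mask_intervals(
    catalog: pd.DataFrame, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    mask = np.zeros(len(catalog), dtype=bool)
    chroms = catalog["chrom"].to_numpy()
    pos = catalog["pos"].to_numpy()
    for chrom, s, e in intervals:
        mask |= (chroms == chrom) & (pos >= s) & (pos < e)
    return mask


def split_spikein(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a methcounts table into (genomic, spike-in) parts."""
    is_spike = table["chrom"] == SPIKEIN_CHROM
    return (
        table.loc[~is_spike].reset_index(drop=True),
        table.loc[is_spike].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: list[str] | list[GeneModel],
    truth: ExpressionTruth,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    n_replicates: int = 3,
    library_size: int = 20_000_000,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a counts matrix; returns (matrix, true tissue-mean table).

    Per-gene per-tissue expected counts are scaled so column sums are near
    ``library_size``; counts are NB(mean, dispersion). Coexpression-module
    members' tissue-mean profiles are affine transforms of the reference
    gene's profile plus Gaussian noise whose variance is calibrated so the
    Pearson correlation with the reference profile is the stated target in
    expectation.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    lengths = pd.Series(
        {
            g.gene_id if isinstance(g, GeneModel) else str(g): (
                g.exonic_length if isinstance(g, GeneModel) else 2_000
            )
            for g in genes
        },
        dtype=float,
    )
    n_genes = len(gene_ids)
    if truth.baseline_means is not None:
        base = np.array([truth.baseline_means[g] for g in gene_ids], dtype=float)
    else:
        base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)

    # expected mean per (gene, tissue), before library scaling
    mean = pd.DataFrame(
        np.tile(base[:, None], (1, len(tissues))), index=gene_ids, columns=list(tissues)
    )
    for gene, tissue_up, lfc in truth.planted_de:
        mean.loc[gene, tissue_up] = mean.loc[gene, tissue_up] * 2.0**lfc

    if truth.coexpression_module is not None:
        if len(tissues) < 3:
            raise ValueError(
                "a coexpression module needs >= 3 tissue classes to carry a "
                "non-trivial correlation structure"
            )
        ref, members, rho = truth.coexpression_module
        # a strongly tissue-specific reference profile (vascular-marker-like)
        ref_profile = np.geomspace(50.0, 3200.0, len(tissues))
        mean.loc[ref] = ref_profile
        for m in members:
            scale = float(mean.loc[m].mean()) / float(np.mean(ref_profile))
            mean.loc[m] = scale * _correlated_profile(ref_profile, rho, rng)

    counts = {}
    sheet = []
    r = 1.0 / truth.dispersion
    for tissue in tissues:
        mu_t = mean[tissue].to_numpy()
        mu_t = mu_t * (library_size / mu_t.sum())
        for rep in range(1, n_replicates + 1):
            sample_id = f"{tissue}_{rep}"
            p = r / (r + mu_t)
            counts[sample_id] = rng.negative_binomial(r, p)
            sheet.append({"sample_id": sample_id, "tissue": tissue, "replicate": rep})
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids),
        samples=pd.DataFrame(sheet),
        lengths=lengths,
    )
    return matrix, mean


def _correlated_profile(
    ref: np.ndarray, rho: float, rng: np.random.Generator, max_tries: int = 500
) -> np.ndarray:
    """A positive tissue profile whose sample Pearson correlation with
    ``ref`` is exactly ``rho``.

    The centred profile is rotated in the orthogonal complement of the
    centred reference; candidate rotations that would drive a tissue mean
    non-positive are rejected and redrawn, which preserves the exact planted
    correlation. Measurement (count) noise then attenuates the realized
    correlation slightly below the target.
    """
    c = ref - ref.mean()
    norm_c = np.linalg.norm(c)
    chat = c / norm_c
    for _ in range(max_tries):
        z = rng.normal(size=len(ref))
        z -= z.mean()
        u = z - (z @ chat) * chat
        norm_u = np.linalg.norm(u)
        if norm_u < 1e-9:
            continue
        d = rho * chat + np.sqrt(1.0 - rho**2) * (u / norm_u)
        profile = ref.mean() + norm_c * d
        if (profile > 0).all():
            return profile
    raise RuntimeError("could not draw a positive correlated profile")


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def write_truth_json(
    path: str | Path,
    meth_truth: MethylomeTruth | None = None,
    expr_truth: ExpressionTruth | None = None,
) -> None:
    """Persist planted ground truth (DMRs, DE genes, module membership)."""
    out: dict = {}
    if meth_truth is not None:
        out["methylome"] = {
            "rates": {
                "CG": meth_truth.rate_cg,
                "CHG": meth_truth.rate_chg,
                "CHH": meth_truth.rate_chh,
            },
            "error_rate": meth_truth.error_rate,
            "coverage_mean": meth_truth.coverage_mean,
            "planted_dmrs": [
                {
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "tissue_high": d.tissue_high,
                    "rate_high": d.rate_high,
                    "rate_low": d.rate_low,
                }
                for d in meth_truth.planted_dmrs
            ],
        }
    if expr_truth is not None:
        out["expression"] = {
            "dispersion": expr_truth.dispersion,
            "planted_de": [
                {"gene_id": g, "tissue_up": t, "log2fc": f}
                for g, t, f in expr_truth.planted_de
            ],
            "coexpression_module": (
                None
                if expr_truth.coexpression_module is None
                else {
                    "reference": expr_truth.coexpression_module[0],
                    "members": list(expr_truth.coexpression_module[1]),
                    "target_r": expr_truth.coexpression_module[2],
                }
            ),
        }
    Path(path).write_text(json.dumps(out, indent=2))
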