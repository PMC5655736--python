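"""Expression normalization, filtering, differential expression and
pairwise-slope coexpression.

Differential expression is a deliberately simple negative-binomial exact
test: median-ratio size factors, a single common dispersion estimated by
method of moments on normalized counts, and a conditional two-sided exact
test on the per-condition count sums, with Benjamini-Hochberg FDR control.
It honours the operation contract (normalize, genewise exact test, DE iff
FDR <= 0.05 with direction from the sign of the log fold-change) without
reproducing any particular package's empirical-Bayes machinery.

Coexpression follows the pairwise-slope construction: each gene's tissue
profile is turned into the vector of RPKM differences over all ordered
tissue pairs, and the Pearson correlation of two slope vectors is the
coexpression score (r >= 0.9 calls a pair coexpressed). This score is
algebraically identical to the plain Pearson correlation of the tissue-mean
vectors, a property the test suite verifies by brute force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

MIN_CPM = 3.0
DE_FDR = 0.05
COEXPR_R = 0.9
ENRICH_FOLD = 1.2
ENRICH_Q = 0.001

_MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size."""
    lib = matrix.library_sizes
    if (lib == 0).any():
        raise ValueError("zero library size")
    return matrix.counts * 1e6 / lib


def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (library * length)."""
    if matrix.lengths is None:
        raise ValueError("gene lengths required for RPKM")
    lib = matrix.library_sizes
    if (lib == 0).any():
        raise ValueError("zero library size")
    return matrix.counts.mul(1e9 / matrix.lengths, axis=0) / lib


def tissue_mean_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-tissue mean RPKM across replicates (genes x tissues)."""
    r = rpkm(matrix)
    return pd.DataFrame(
        {t: r[matrix.samples_for(t)].mean(axis=1) for t in matrix.tissues}
    )


def expressed_filter(
    matrix: ExpressionMatrix, tissue: str, min_cpm: float = MIN_CPM
) -> set[str]:
    """Genes with CPM >= ``min_cpm`` in every replicate of ``tissue``."""
    cols = matrix.samples_for(tissue)
    if not cols:
        raise ValueError(f"no samples for tissue {tissue!r}")
    keep = (cpm(matrix)[cols] >= min_cpm).all(axis=1)
    return set(matrix.counts.index[keep])


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference."""
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample; cannot normalize")
    logc = np.log(counts.loc[usable])
    ref = logc.mean(axis=1)
    ratios = logc.sub(ref, axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / stats.gmean(sf)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    table: pd.DataFrame  # gene_id index: logFC, p_value, fdr, direction
    dispersion: float
    tissue_a: str
    tissue_b: str

    def significant(self, fdr: float = DE_FDR) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr]


def _common_dispersion(norm: pd.DataFrame, groups: list[list[str]]) -> float:
    """Method-of-moments common NB dispersion on normalized counts."""
    phis = []
    for cols in groups:
        sub = norm[cols]
        if len(cols) < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phis.append(((v[ok] - m[ok]) / m[ok] ** 2).to_numpy())
    if not phis:
        return _MIN_DISPERSION
    pooled = np.concatenate(phis)
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        return _MIN_DISPERSION
    return float(max(np.median(pooled), _MIN_DISPERSION))


def _nb_exact_p(ka: int, kb: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional two-sided NB exact test on per-condition count sums.

    The sum of n i.i.d. NB(mu, phi) is NB(n*mu, phi/n); conditioning on
    ka + kb = s, the p-value sums the probabilities of all splits no more
    likely than the observed one.
    """
    s = ka + kb
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    k = np.arange(s + 1)
    logp = stats.nbinom.logpmf(k, r_a, p_a) + stats.nbinom.logpmf(s - k, r_b, p_b)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[ka]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def differential_expression(
    matrix: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    fdr: float = DE_FDR,
) -> DeResult:
    """Simplified NB exact-test differential expression between two tissues.

    All-zero genes are excluded. ``direction`` is ``up_in_<tissue>`` by the
    sign of logFC (log2 of B over A); a gene is DE iff its BH FDR <= ``fdr``.
    """
    cols_a = matrix.samples_for(tissue_a)
    cols_b = matrix.samples_for(tissue_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per tissue")
    counts = matrix.counts[cols_a + cols_b]
    counts = counts[counts.sum(axis=1) > 0]
    sf = median_ratio_size_factors(counts)
    norm = counts / sf
    phi = _common_dispersion(norm, [cols_a, cols_b])

    ka = norm[cols_a].sum(axis=1).round().astype(int)
    kb = norm[cols_b].sum(axis=1).round().astype(int)
    n_a, n_b = len(cols_a), len(cols_b)
    pvals = np.array(
        [_nb_exact_p(int(a), int(b), n_a, n_b, phi) for a, b in zip(ka, kb)]
    )
    mean_a = ka / n_a
    mean_b = kb / n_b
    logfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": pvals,
            "fdr": qvals,
            "direction": np.where(
                logfc >= 0, f"up_in_{tissue_b}", f"up_in_{tissue_a}"
            ),
        },
        index=counts.index,
    )
    return DeResult(table=table, dispersion=phi, tissue_a=tissue_a, tissue_b=tissue_b)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def replicate_qc(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise replicate r^2 of FPKM vectors within each tissue class."""
    values = rpkm(matrix)
    rows = []
    for tissue in matrix.tissues:
        cols = matrix.samples_for(tissue)
        for a, b in combinations(cols, 2):
            r = float(np.corrcoef(values[a], values[b])[0, 1])
            rows.append(
                {"tissue": tissue, "sample_a": a, "sample_b": b, "r2": r * r}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vascular-enrichment filter
# ---------------------------------------------------------------------------

def enrichment_filter(
    expr_by_class: pd.DataFrame,
    focal_classes: list[str],
    contrast_classes: list[str],
    qvalues: pd.Series,
    fold: float = ENRICH_FOLD,
    q_max: float = ENRICH_Q,
) -> set[str]:
    """Genes whose abundance in some focal class is > ``fold`` times every
    contrast class, at significance q <= ``q_max``.

    ``expr_by_class`` is genes x classes (e.g. tissue-mean RPKM).
    """
    focal = expr_by_class[focal_classes]
    contrast_max = expr_by_class[contrast_classes].max(axis=1)
    passes_fold = focal.gt(fold * contrast_max, axis=0).any(axis=1)
    q = qvalues.reindex(expr_by_class.index)
    return set(expr_by_class.index[passes_fold & (q <= q_max)])


# ---------------------------------------------------------------------------
# pairwise-slope coexpression
# ---------------------------------------------------------------------------

def pairwise_slopes(profile: np.ndarray) -> np.ndarray:
    """Differences x_j - x_i over all ordered tissue pairs i != j.

    Both directions are kept, so the slope vector always has mean zero;
    with this construction the Pearson correlation of two slope vectors is
    exactly the Pearson correlation of the underlying tissue profiles.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 tissue classes for slope correlation")
    i, j = np.where(~np.eye(len(x), dtype=bool))
    return x[j] - x[i]


def pairwise_slope_correlation(
    reference_profile: np.ndarray, query_profile: np.ndarray
) -> float:
    """Pearson correlation of the pairwise-slope vectors of two tissue
    profiles. Returns NaN (with a warning) for a constant profile."""
    a = pairwise_slopes(reference_profile)
    b = pairwise_slopes(query_profile)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant tissue profile: slope correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def coexpression_scan(
    matrix: ExpressionMatrix,
    reference_gene: str,
    candidate_genes: list[str] | None = None,
    r_threshold: float = COEXPR_R,
) -> pd.DataFrame:
    """Rank genes by pairwise-slope correlation with a reference gene's
    tissue-mean RPKM profile."""
    means = tissue_mean_rpkm(matrix)
    if reference_gene not in means.index:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    ref = means.loc[reference_gene].to_numpy()
    genes = (
        [g for g in means.index if g != reference_gene]
        if candidate_genes is None
        else [g for g in candidate_genes if g != reference_gene]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs = [
            pairwise_slope_correlation(ref, means.loc[g].to_numpy()) for g in genes
        ]
    out = pd.DataFrame(
        {"query_gene": genes, "r": rs}
    )
    out["coexpressed"] = out["r"] >= r_threshold
    out.insert(0, "reference_gene", reference_gene)
    return out.sort_values("r", ascending=False).reset_index(drop=True)
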