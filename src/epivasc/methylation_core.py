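"""Replicate pooling, binomial methylation calling, and methylome QC.

The caller follows the standard whole-genome bisulfite workflow: replicate
count tables are pooled per cytosine, the bisulfite non-conversion (error)
rate is estimated from an unmethylated spike-in control, and each cytosine
with pooled depth >= 4 is tested with an exact upper-tail binomial test
B(x >= k; n, p) against that error rate. Benjamini-Hochberg correction is
applied per sample across all contexts jointly, and sites with q <= 0.01
are called methylated.

Statuses: ``methylated`` / ``unmethylated`` for tested sites, ``uncallable``
for sites below the coverage floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import METHCOUNTS_COLUMNS

MIN_COVERAGE = 4
SITE_FDR = 0.01
#: lower bound of the spike-in-estimated error-rate range, used as a floor
ERROR_RATE_FLOOR = 1e-4
ERROR_RATE_RANGE = (1e-4, 3.3e-3)

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_UNCALLABLE = "uncallable"


@dataclass
class MethylationCallSet:
    """Per-site binomial methylation calls for one sample."""

    sample_id: str
    sites: pd.DataFrame  # METHCOUNTS_COLUMNS + p_value, q_value, status
    error_rate: float

    def status_vector(self) -> pd.Series:
        """1/0 methylation status over callable sites, indexed by
        (chrom, pos, strand)."""
        callable_ = self.sites[self.sites["status"] != STATUS_UNCALLABLE]
        idx = pd.MultiIndex.from_frame(callable_[["chrom", "pos", "strand"]])
        return pd.Series(
            (callable_["status"] == STATUS_METHYLATED).to_numpy(dtype=np.int8),
            index=idx,
        )


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool methcounts tables per (chrom, pos, strand): n and k are summed
    over the replicates in which the site appears."""
    if not tables:
        raise ValueError("no replicate tables to merge")
    cat = pd.concat(tables, ignore_index=True)
    grouped = cat.groupby(["chrom", "pos", "strand"], sort=True)
    ctx = grouped["context"].agg(["first", "nunique"])
    if (ctx["nunique"] > 1).any():
        bad = ctx[ctx["nunique"] > 1].index[0]
        raise ValueError(f"conflicting context annotations at {bad}")
    pooled = grouped[["meth", "total"]].sum().reset_index()
    pooled["context"] = ctx["first"].to_numpy()
    return pooled[METHCOUNTS_COLUMNS]


def estimate_error_rate(spikein: pd.DataFrame) -> float:
    """Non-conversion rate = pooled methylated reads / pooled reads over all
    spike-in cytosines. Warns when the estimate leaves the expected
    0.01-0.33% range."""
    if len(spikein) == 0 or spikein["total"].sum() == 0:
        raise ValueError("empty spike-in table: cannot estimate error rate")
    rate = float(spikein["meth"].sum() / spikein["total"].sum())
    if rate == 0.0:
        rate = ERROR_RATE_FLOOR
    if not ERROR_RATE_RANGE[0] <= rate <= ERROR_RATE_RANGE[1]:
        warnings.warn(
            f"spike-in error rate {rate:.2e} outside the expected range "
            f"[{ERROR_RATE_RANGE[0]:.0e}, {ERROR_RATE_RANGE[1]:.1e}]",
            stacklevel=2,
        )
    return rate


def binomial_tail(k, n, p: float):
    """Exact upper-tail binomial probability P(X >= k | n, p).

    Accepts scalars or arrays for ``k`` and ``n``.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if (k < 0).any() or (k > n).any():
        raise ValueError("require 0 <= k <= n")
    out = stats.binom.sf(k - 1, n, p)
    return float(out) if out.ndim == 0 else out


def call_methylation(
    pooled: pd.DataFrame,
    error_rate: float,
    sample_id: str = "sample",
    min_cov: int = MIN_COVERAGE,
    fdr: float = SITE_FDR,
) -> MethylationCallSet:
    """Binomial methylation calls on a pooled count table.

    Sites with depth < ``min_cov`` are flagged uncallable and excluded from
    testing; BH correction runs across all tested sites of the sample (all
    contexts jointly); methylated iff q <= ``fdr``.
    """
    if len(pooled) == 0:
        raise ValueError("empty pooled table")
    if error_rate <= 0:
        error_rate = ERROR_RATE_FLOOR
    sites = pooled[METHCOUNTS_COLUMNS].copy()
    tested = (sites["total"] >= min_cov).to_numpy()
    p_value = np.full(len(sites), np.nan)
    q_value = np.full(len(sites), np.nan)
    status = np.full(len(sites), STATUS_UNCALLABLE, dtype=object)
    if tested.any():
        pv = binomial_tail(
            sites.loc[tested, "meth"].to_numpy(),
            sites.loc[tested, "total"].to_numpy(),
            error_rate,
        )
        p_value[tested] = pv
        _, qv, _, _ = multipletests(pv, method="fdr_bh")
        q_value[tested] = qv
        status[tested] = np.where(qv <= fdr, STATUS_METHYLATED, STATUS_UNMETHYLATED)
    sites["p_value"] = p_value
    sites["q_value"] = q_value
    sites["status"] = status
    return MethylationCallSet(sample_id=sample_id, sites=sites, error_rate=error_rate)


def weighted_level(
    sites: pd.DataFrame,
    context: str | None = None,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Weighted methylation level: total methylated reads / total reads over
    the selected sites (coverage-weighted, not a mean of per-site fractions).

    Raises on an empty selection (undefined level).
    """
    sel = sites
    if context is not None:
        sel = sel[sel["context"] == context]
    if chrom is not None:
        sel = sel[sel["chrom"] == chrom]
    if start is not None:
        sel = sel[sel["pos"] >= start]
    if end is not None:
        sel = sel[sel["pos"] < end]
    total = sel["total"].sum()
    if len(sel) == 0 or total == 0:
        raise ValueError("weighted level undefined: no covered sites selected")
    return float(sel["meth"].sum() / total)


def replicate_correlation(
    calls_a: MethylationCallSet, calls_b: MethylationCallSet
) -> float:
    """Pearson r of 0/1 methylation status over sites callable in both.

    Returns NaN (with a warning) when either status vector is constant.
    """
    a = calls_a.status_vector()
    b = calls_b.status_vector()
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared callable sites")
    av = a.loc[shared].to_numpy(dtype=float)
    bv = b.loc[shared].to_numpy(dtype=float)
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("constant methylation status vector: r undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


# ---------------------------------------------------------------------------
# methylation-state PCA
# ---------------------------------------------------------------------------

def build_state_matrix(
    calls_by_sample: dict[str, MethylationCallSet], context: str | None = None
) -> pd.DataFrame:
    """Binary methylation-state matrix: rows = samples (tissue x replicate),
    columns = sites callable (depth >= 4) in *every* sample.

    ``context`` restricts the site universe to one methylation context.
    """
    vectors = {}
    shared = None
    for sid, calls in calls_by_sample.items():
        sites = calls.sites
        if context is not None:
            sites = sites[sites["context"] == context]
        callable_ = sites[sites["status"] != STATUS_UNCALLABLE]
        idx = pd.MultiIndex.from_frame(callable_[["chrom", "pos", "strand"]])
        vec = pd.Series(
            (callable_["status"] == STATUS_METHYLATED).to_numpy(dtype=np.int8),
            index=idx,
        )
        vectors[sid] = vec
        shared = vec.index if shared is None else shared.intersection(vec.index)
    if shared is None or len(shared) == 0:
        raise ValueError("no sites callable in every sample")
    return pd.DataFrame(
        {sid: vec.loc[shared].to_numpy() for sid, vec in vectors.items()},
        index=shared,
    ).T


def methylation_pca(
    state_matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a binary methylation-state matrix.

    Columns (sites) are centred; components are ordered by variance
    explained, with a deterministic sign convention (the largest-magnitude
    loading of each component is positive). Returns (sample coordinates,
    variance-explained fractions). An all-constant matrix yields zero
    coordinates and zero variance.
    """
    if state_matrix.shape[0] < 3 or state_matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 sites")
    x = state_matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    k = min(x.shape) if n_components is None else min(n_components, min(x.shape))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0.0:
        coords = np.zeros((x.shape[0], k))
        var_explained = np.zeros(k)
    else:
        # sign convention: largest-|loading| entry of each component positive
        for i in range(len(s)):
            j = int(np.argmax(np.abs(vt[i])))
            if vt[i, j] < 0:
                vt[i] *= -1.0
                u[:, i] *= -1.0
        coords = (u * s)[:, :k]
        var_explained = (s**2 / total_var)[:k]
    out = pd.DataFrame(
        coords,
        index=state_matrix.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return out, var_explained
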