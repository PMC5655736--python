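import numpy as np
import pandas as pd
import pytest

from epivasc.io_formats import METHCOUNTS_COLUMNS
from epivasc.synthetic_data import (
    MethylomeTruth,
    generate_gene_models,
    generate_genome,
    simulate_methylome,
)


def make_methcounts(rows):
    """Build a methcounts table from (chrom, pos, strand, context, meth, total)
    tuples (positions 0-based, as used internally)."""
    return pd.DataFrame(rows, columns=METHCOUNTS_COLUMNS)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(1, 100_000, 0.44, seed=7)


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return generate_gene_models(small_genome, 8, seed=11)


@pytest.fixture(scope="session")
def small_methylome(small_genome, small_genes):
    """Two tissues x 2 replicates at defaults, with one planted DMR."""
    from epivasc.synthetic_data import PlantedDmr

    truth = MethylomeTruth(
        planted_dmrs=[PlantedDmr("chr1", 60_000, 60_300, "vascular")],
        coverage_mean=8.0,
    )
    tables = simulate_methylome(
        small_genome,
        small_genes,
        truth,
        tissues=("vascular", "nonvascular"),
        n_replicates=2,
        seed=13,
    )
    return truth, tables


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the code paths they check)
# ---------------------------------------------------------------------------

def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct pmf summation with exact binomial coefficients."""
    import math

    return math.fsum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def hypergeom_pmf_fraction(x: int, n_pop: int, big_k: int, n_draw: int):
    from fractions import Fraction
    from math import comb

    return Fraction(
        comb(big_k, x) * comb(n_pop - big_k, n_draw - x), comb(n_pop, n_draw)
    )


def hypergeom_upper_oracle(a: int, n_pop: int, big_k: int, n_draw: int) -> float:
    """P(X >= a) for the hypergeometric by exact-rational enumeration."""
    hi = min(n_draw, big_k)
    return float(
        sum(hypergeom_pmf_fraction(x, n_pop, big_k, n_draw) for x in range(a, hi + 1))
    )


def fisher_two_sided_oracle(ma: int, ua: int, mb: int, ub: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing probabilities <= the observed table's."""
    n_pop = ma + ua + mb + ub
    big_k = ma + mb  # methylated margin
    n_draw = ma + ua  # sample A margin
    lo = max(0, n_draw - (n_pop - big_k))
    hi = min(n_draw, big_k)
    obs = hypergeom_pmf_fraction(ma, n_pop, big_k, n_draw)
    return float(
        sum(
            p
            for x in range(lo, hi + 1)
            if (p := hypergeom_pmf_fraction(x, n_pop, big_k, n_draw)) <= obs
        )
    )


def bh_reject_oracle(pvals, q: float):
    """Benjamini-Hochberg by the textbook definition: sort, find the largest
    i with p_(i) <= i*q/m, reject all p-values up to that rank."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing[-1] + 1]] = True
    return reject
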