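"""Over-representation tests: GO-term enrichment with Bonferroni correction
and transcription-factor-family enrichment by Fisher exact test.

Both tests are one-sided (over-representation only): the GO test is the
upper-tail hypergeometric probability of drawing at least the observed
number of term members into the study set, Bonferroni-corrected over the
terms with at least one study hit (enriched iff corrected p < 0.05). The
TF-family test compares the fraction of a family's members in the focal
(e.g. vascular-expressed) set against the genome-wide fraction.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

GO_ALPHA = 0.05


def read_associations(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF-style association TSV (gene_id, term_id[, aspect]) into a
    term -> gene-set mapping."""
    df = pd.read_csv(
        path, sep="\t", comment="!", header=None, usecols=[0, 1],
        names=["gene_id", "term_id"], dtype=str,
    )
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id"):
        out[str(term)] = set(grp["gene_id"])
    return out


def annotated_universe(annotations: dict[str, set[str]]) -> set[str]:
    """All genes carrying at least one annotation (the default population)."""
    universe: set[str] = set()
    for genes in annotations.values():
        universe |= genes
    return universe


def hypergeom_upper_tail(a: int, n_study: int, big_k: int, n_pop: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=n_pop, K=big_k, n=n_study)."""
    return float(stats.hypergeom.sf(a - 1, n_pop, big_k, n_study))


def go_enrichment(
    study_genes: set[str],
    annotations: dict[str, set[str]],
    population_genes: set[str] | None = None,
    alpha: float = GO_ALPHA,
) -> pd.DataFrame:
    """One-sided hypergeometric GO over-representation with Bonferroni.

    The population defaults to all annotated genes; the study set is
    intersected with the population. Terms with zero study hits are not
    tested (and do not count toward the Bonferroni factor).
    """
    population = (
        annotated_universe(annotations)
        if population_genes is None
        else set(population_genes) & annotated_universe(annotations)
    )
    study = set(study_genes) & population
    if not study:
        raise ValueError("no annotated study genes in the population")
    n_pop, n_study = len(population), len(study)
    rows = []
    for term, genes in annotations.items():
        members = genes & population
        a = len(members & study)
        if a == 0:
            continue
        rows.append(
            {
                "term_id": term,
                "study_hits": a,
                "study_size": n_study,
                "population_hits": len(members),
                "population_size": n_pop,
                "p_value": hypergeom_upper_tail(a, n_study, len(members), n_pop),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(out)
    out["p_bonferroni"] = (out["p_value"] * m).clip(upper=1.0)
    out["enriched"] = out["p_bonferroni"] < alpha
    return out.sort_values("p_value").reset_index(drop=True)


def tf_family_enrichment(
    family_map: dict[str, set[str]],
    focal_gene_set: set[str],
    genome_size: int,
    focal_set_size: int | None = None,
) -> pd.DataFrame:
    """Per-family one-sided Fisher test for focal (vascular) enrichment.

    For each family the 2x2 table contrasts family members inside/outside
    the focal set against the remaining genome; the reported p is the
    upper-tail hypergeometric probability (over-representation).
    """
    if focal_set_size is None:
        focal_set_size = len(focal_gene_set)
    if focal_set_size > genome_size:
        raise ValueError("focal set larger than genome")
    rows = []
    for family, members in family_map.items():
        size = len(members)
        if size == 0:
            raise ValueError(f"empty TF family {family!r}")
        if size > genome_size:
            raise ValueError(f"family {family!r} larger than the genome")
        hits = len(members & focal_gene_set)
        rows.append(
            {
                "family": family,
                "family_size": size,
                "focal_hits": hits,
                "genome_size": genome_size,
                "focal_set_size": focal_set_size,
                "p_value": hypergeom_upper_tail(
                    hits, size, focal_set_size, genome_size
                ),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)
    )
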