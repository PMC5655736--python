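"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes simulate -> call -> pca -> profile -> dmr ->
hypermethylation -> expression -> coexpression (-> enrichment when an
association file is given) on a synthetic dataset, writing every
intermediate in the plain-text formats of :mod:`epivasc.io_formats` plus a
manifest recording the package version, seed and a parameter hash. All
stages are pure functions of (inputs, config, seed), so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dmr_detection import (
    GENE_FLANK,
    HYPER_FDR,
    HYPER_MIN_CYTOSINES,
    LOW_CUT,
    HIGH_CUT,
    MIN_CYTOSINES,
    WINDOW_ALPHA,
    WINDOW_SIZE,
    WINDOW_STEP,
    associate_genes,
    build_windows,
    classify_dmrs,
    cluster_dmrs,
    dmr_level_matrix,
    hypermethylated_genes,
    merge_windows,
    score_windows,
)
from .enrichment import GO_ALPHA, go_enrichment, read_associations
from .expression_analysis import (
    COEXPR_R,
    DE_FDR,
    ENRICH_FOLD,
    ENRICH_Q,
    MIN_CPM,
    coexpression_scan,
    differential_expression,
    expressed_filter,
    replicate_qc,
)
from .genic_profiles import profile_sample
from .io_formats import write_bed, write_counts_matrix, write_fasta, write_methcounts
from .methylation_core import (
    MIN_COVERAGE,
    SITE_FDR,
    ERROR_RATE_FLOOR,
    build_state_matrix,
    call_methylation,
    estimate_error_rate,
    merge_replicates,
    methylation_pca,
    weighted_level,
)
from .synthetic_data import (
    DEFAULT_TISSUES,
    ExpressionTruth,
    MethylomeTruth,
    PlantedDmr,
    generate_gene_models,
    generate_genome,
    simulate_expression,
    simulate_methylome,
    split_spikein,
    write_truth_json,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; the defaults are the study's published
    thresholds."""

    seed: int = 0
    outdir: str = "epivasc_run"

    # synthetic-data scale
    n_chrom: int = 1
    chrom_length: int = 300_000
    gc_fraction: float = 0.44
    n_genes: int = 40
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 3
    coverage_mean: float = 8.0
    error_rate: float = 0.002
    n_planted_dmrs: int = 10
    dmr_length: int = 300
    library_size: int = 2_000_000
    n_expr_genes: int = 1000
    n_de_genes: int = 25
    de_log2fc: float = 3.0
    module_size: int = 10
    module_target_r: float = 0.95
    dispersion: float = 0.05

    # contrasts
    methylation_contrast: tuple[str, str] = ("vascular", "nonvascular")
    expression_contrast: tuple[str, str] = ("vascular", "nonvascular")

    # published analysis thresholds
    min_coverage: int = MIN_COVERAGE
    site_fdr: float = SITE_FDR
    error_rate_floor: float = ERROR_RATE_FLOOR
    window_size: int = WINDOW_SIZE
    window_step: int = WINDOW_STEP
    min_cytosines: int = MIN_CYTOSINES
    window_alpha: float = WINDOW_ALPHA
    low_cut: float = LOW_CUT
    high_cut: float = HIGH_CUT
    gene_flank: int = GENE_FLANK
    hyper_min_cytosines: int = HYPER_MIN_CYTOSINES
    hyper_fdr: float = HYPER_FDR
    min_cpm: float = MIN_CPM
    de_fdr: float = DE_FDR
    coexpr_r: float = COEXPR_R
    enrich_fold: float = ENRICH_FOLD
    enrich_q: float = ENRICH_Q
    go_alpha: float = GO_ALPHA

    kmeans_k: int = 4
    annotations_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "methylation_contrast", "expression_contrast"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        for t in (*self.methylation_contrast, *self.expression_contrast):
            if t not in self.tissues:
                raise ValueError(f"contrast tissue {t!r} not among {self.tissues}")

    def parameter_hash(self) -> str:
        params = dataclasses.asdict(self)
        params.pop("outdir")  # paths are not part of the scientific parameters
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated dataset; returns a result
    summary (also written as ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.annotations_path is not None and not Path(config.annotations_path).exists():
        raise FileNotFoundError(config.annotations_path)

    # --- simulate -----------------------------------------------------------
    logger.info("simulating genome and methylomes")
    genome = generate_genome(
        config.n_chrom, config.chrom_length, config.gc_fraction, seed=config.seed
    )
    genes = generate_gene_models(genome, config.n_genes, seed=config.seed + 1)
    tissue_high, tissue_low = config.methylation_contrast
    rng_positions = range(
        5_000, config.chrom_length - 5_000,
        max(config.dmr_length + 5_000,
            (config.chrom_length - 10_000) // max(config.n_planted_dmrs, 1)),
    )
    planted = [
        PlantedDmr("chr1", p, p + config.dmr_length, tissue_high)
        for p in list(rng_positions)[: config.n_planted_dmrs]
    ]
    meth_truth = MethylomeTruth(
        planted_dmrs=planted,
        error_rate=config.error_rate,
        coverage_mean=config.coverage_mean,
    )
    tables = simulate_methylome(
        genome, genes, meth_truth, config.tissues, config.n_replicates,
        seed=config.seed + 2,
    )
    expr_genes = [f"gene{i + 1:05d}" for i in range(config.n_expr_genes)]
    rng_de = expr_genes[: config.n_de_genes]
    module_members = expr_genes[config.n_de_genes: config.n_de_genes + config.module_size]
    with_module = len(config.tissues) >= 3
    expr_truth = ExpressionTruth(
        planted_de=[
            (g, config.expression_contrast[i % 2], config.de_log2fc)
            for i, g in enumerate(rng_de)
        ],
        coexpression_module=(
            (expr_genes[-1], module_members, config.module_target_r)
            if with_module
            else None
        ),
        dispersion=config.dispersion,
    )
    matrix, _ = simulate_expression(
        expr_genes, expr_truth, config.tissues, config.n_replicates,
        config.library_size, seed=config.seed + 3,
    )

    write_fasta(genome, out / "genome.fa")
    for (tissue, rep), table in tables.items():
        write_methcounts(table, out / f"meth_{tissue}_{rep}.tsv")
    write_counts_matrix(matrix, out / "counts.tsv", out / "samples.tsv")
    write_truth_json(out / "truth.json", meth_truth, expr_truth)

    # --- methylation calling ------------------------------------------------
    logger.info("pooling replicates and calling methylation")
    calls = {}
    per_replicate_calls = {}
    error_rates = {}
    for tissue in config.tissues:
        reps = [tables[(tissue, r)] for r in range(1, config.n_replicates + 1)]
        split = [split_spikein(t) for t in reps]
        pooled = merge_replicates([g for g, _ in split])
        spike = merge_replicates([s for _, s in split])
        err = estimate_error_rate(spike)
        error_rates[tissue] = err
        calls[tissue] = call_methylation(
            pooled, err, sample_id=tissue,
            min_cov=config.min_coverage, fdr=config.site_fdr,
        )
        for r, (genomic, _) in enumerate(split, start=1):
            per_replicate_calls[f"{tissue}_{r}"] = call_methylation(
                genomic, err, sample_id=f"{tissue}_{r}",
                min_cov=config.min_coverage, fdr=config.site_fdr,
            )
        calls[tissue].sites.to_csv(out / f"calls_{tissue}.tsv", sep="\t", index=False)

    genome_levels = {
        tissue: {
            ctx: weighted_level(cs.sites, context=ctx)
            for ctx in ("CG", "CHG", "CHH")
        }
        for tissue, cs in calls.items()
    }

    # --- PCA ----------------------------------------------------------------
    logger.info("methylation-state PCA")
    state = build_state_matrix(per_replicate_calls)
    coords, var_exp = methylation_pca(state)
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t")

    # --- metagene profiles --------------------------------------------------
    logger.info("metagene profiles")
    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    profile_table = {}
    for tissue in config.tissues:
        prof = profile_sample(calls[tissue], genes, "CG", chrom_lengths=chrom_lengths)
        profile_table[tissue] = prof.levels
    pd.DataFrame(profile_table).to_csv(out / "profiles_CG.tsv", sep="\t", index_label="bin")

    # --- DMRs ---------------------------------------------------------------
    logger.info("DMR detection: %s vs %s", tissue_high, tissue_low)
    windows = build_windows(
        calls[tissue_high], calls[tissue_low], genome,
        window_size=config.window_size, step=config.window_step,
        min_cytosines=config.min_cytosines, min_cov=config.min_coverage,
    )
    score_windows(windows)
    regions = merge_windows(windows, alpha=config.window_alpha)
    dmrs = classify_dmrs(
        regions, calls[tissue_high], calls[tissue_low],
        low_cut=config.low_cut, high_cut=config.high_cut,
        min_cov=config.min_coverage,
    )
    associate_genes(dmrs, genes, flank=config.gene_flank)
    write_bed(dmrs, out / "dmrs.bed")
    pd.DataFrame(
        [
            {"dmr": d.name, "gene_id": g, "relation": rel}
            for d in dmrs
            for g, rel in d.associated_genes
        ]
    ).to_csv(out / "dmr_gene_associations.tsv", sep="\t", index=False)

    cluster_summary = None
    if len(dmrs) >= config.kmeans_k:
        levels = dmr_level_matrix(dmrs, calls)
        if len(levels) >= config.kmeans_k:
            labels, silhouette = cluster_dmrs(levels, k=config.kmeans_k, seed=config.seed)
            labels.to_csv(out / "dmr_clusters.tsv", sep="\t")
            cluster_summary = {
                "k": config.kmeans_k,
                "silhouette": None if pd.isna(silhouette) else float(silhouette),
            }

    hyper = hypermethylated_genes(
        calls[tissue_high], genes, "CG",
        min_cytosines=config.hyper_min_cytosines, fdr=config.hyper_fdr,
    )
    hyper.to_csv(out / "hypermethylated_genes.tsv", sep="\t", index=False)

    # --- expression ---------------------------------------------------------
    logger.info("expression analysis")
    tissue_ea, tissue_eb = config.expression_contrast
    de = differential_expression(matrix, tissue_ea, tissue_eb, fdr=config.de_fdr)
    de.table.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
    expressed = {
        t: sorted(expressed_filter(matrix, t, min_cpm=config.min_cpm))
        for t in config.tissues
    }
    (out / "expressed_genes.json").write_text(json.dumps(expressed, indent=2))
    qc = replicate_qc(matrix)
    qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)

    coexpr = None
    if with_module:
        coexpr = coexpression_scan(
            matrix, expr_genes[-1], r_threshold=config.coexpr_r
        )
        coexpr.to_csv(out / "coexpression.tsv", sep="\t", index=False)

    enrichment_rows = None
    if config.annotations_path is not None:
        annotations = read_associations(config.annotations_path)
        study = set(de.significant(config.de_fdr).index)
        enr = go_enrichment(study, annotations, alpha=config.go_alpha)
        enr.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        enrichment_rows = int(len(enr))

    manifest = {
        "package": "epivasc",
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "error_rates": error_rates,
        "genome_weighted_levels": genome_levels,
        "n_windows_tested": int(sum(w.tested for w in windows)),
        "n_candidate_regions": len(regions),
        "n_dmrs": len(dmrs),
        "n_hypermethylated_genes": int(hyper["significant"].sum()) if len(hyper) else 0,
        "n_de_genes": int(len(de.significant(config.de_fdr))),
        "n_coexpressed": (
            int(coexpr["coexpressed"].sum()) if coexpr is not None else None
        ),
        "pca_variance_explained": [float(v) for v in var_exp[:3]],
        "dmr_clusters": cluster_summary,
        "go_terms_tested": enrichment_rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
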