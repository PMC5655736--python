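"""Readers and writers for the on-disk formats shared by the whole pipeline.

Conventions
-----------
* All *internal* coordinates are 0-based half-open intervals; a cytosine site
  is a 0-based point position on one strand.
* Methcounts tables on disk carry 1-based positions (the common CX-report
  convention); the reader/writer pair converts, so round-trips are exact.
* Methylation contexts are restricted to ``CG``, ``CHG`` and ``CHH`` (H = A,
  C or T); CHH absorbs every non-CG/CHG cytosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

CONTEXTS = ("CG", "CHG", "CHH")

#: column order of a methcounts table (positions 0-based once in memory)
METHCOUNTS_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """A small genome held in memory as uppercase DNA strings."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names")
        for name in self.chrom_names:
            if len(self.sequences[name]) == 0:
                raise FormatError(f"empty sequence for {name!r}")

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneModel:
    """Gene span with ordered exons, all 0-based half-open.

    Exons are kept in genomic order regardless of strand; transcriptional
    orientation is applied where it matters (profile binning).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        merged = _merge_intervals(self.exons)
        if len(merged) != len(self.exons):
            warnings.warn(
                f"overlapping exons merged for gene {self.gene_id}", stacklevel=2
            )
        self.exons = merged
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"exon [{s},{e}) outside gene span of {self.gene_id}"
                )
        if self.exonic_length < 1:
            raise FormatError(f"gene {self.gene_id} has no exonic sequence")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            raise FormatError(f"empty interval [{s},{e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with gene lengths and a sample sheet.

    ``counts`` is genes (rows) by sample ids (columns); ``samples`` carries
    columns ``sample_id``, ``tissue``, ``replicate``. Library sizes are the
    raw column sums.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise FormatError("negative counts")
        missing = set(self.counts.columns) - set(self.samples["sample_id"])
        if missing:
            raise FormatError(f"samples missing from sample sheet: {sorted(missing)}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise FormatError("gene lengths must be positive for all genes")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_for(self, tissue: str) -> list[str]:
        sheet = self.samples
        return list(sheet.loc[sheet["tissue"] == tissue, "sample_id"])

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.samples["tissue"]))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased)."""
    names: list[str] = []
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # pragma: no cover - biopython detail
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not names:
        raise FormatError(f"no sequences found in {path}")
    return GenomeSequence(names, seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# methcounts tables
# ---------------------------------------------------------------------------

def read_methcounts(path: str | Path) -> pd.DataFrame:
    """Read a 6-column methcounts TSV into a validated table.

    On-disk positions are 1-based; the returned frame holds 0-based positions
    in ``METHCOUNTS_COLUMNS`` order.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=METHCOUNTS_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    if df.empty:
        raise FormatError(f"empty methcounts file {path}")
    for col in ("pos", "meth", "total"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise FormatError(f"non-integer values in column {col!r} of {path}")
    df["pos"] = df["pos"] - 1
    return validate_methcounts(df, source=str(path))


def validate_methcounts(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate invariants of an in-memory methcounts table and sort it."""
    if (df["pos"] < 0).any():
        raise FormatError(f"{source}: non-positive position")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{source}: bad strand token")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        tok = df.loc[bad_ctx, "context"].iloc[0]
        raise FormatError(f"{source}: unknown context token {tok!r}")
    if (df["meth"] > df["total"]).any():
        raise FormatError(f"{source}: meth_count exceeds total_count")
    if (df["total"] <= 0).any():
        raise FormatError(f"{source}: non-positive total_count")
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        raise FormatError(f"{source}: duplicate (chrom, pos, strand)")
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def write_methcounts(df: pd.DataFrame, path: str | Path) -> None:
    """Write a methcounts table, converting positions back to 1-based."""
    out = df[METHCOUNTS_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models (BED12 / GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (preferred) or GFF3.

    The format is sniffed from the first non-comment line.
    """
    path = Path(path)
    first = None
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first is None:
        raise FormatError(f"no records in {path}")
    if len(first.rstrip("\n").split("\t")) >= 12 and first.split("\t")[6].strip().isdigit():
        return _read_bed12(path)
    return _read_gff3(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 requires 12 fields")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise FormatError(f"{path}:{ln}: blockCount mismatch")
            exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    gene_rows: dict[str, tuple[str, str, int, int]] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{ln}: GFF3 requires 9 fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attrd.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{ln}: gene without ID attribute")
                gene_rows[gid] = (chrom, strand, int(start) - 1, int(end))
            elif ftype == "exon":
                parent = attrd.get("Parent") or attrd.get("ID")
                if parent is None:
                    raise FormatError(f"{path}:{ln}: exon without Parent")
                exon_rows.setdefault(parent.split(",")[0], []).append(
                    (int(start) - 1, int(end))
                )
    genes = []
    for gid, (chrom, strand, start, end) in gene_rows.items():
        exons = exon_rows.get(gid, [(start, end)])
        genes.append(GeneModel(gid, chrom, strand, start, end, exons))
    return genes


def write_bed(regions, path: str | Path) -> None:
    """Write regions as BED; score carries -log10(p) capped at 1000.

    ``regions`` is an iterable of objects (or mappings) with ``chrom``,
    ``start``, ``end`` and optional ``name`` / ``p_value`` attributes.
    Output is sorted by (chrom, start).
    """

    def get(r, key, default=None):
        if isinstance(r, dict):
            return r.get(key, default)
        return getattr(r, key, default)

    rows = []
    for i, r in enumerate(regions):
        p = get(r, "p_value")
        if p is None or p <= 0:
            score = 1000.0 if p is not None else 0.0
        else:
            score = min(1000.0, -np.log10(p))
        rows.append(
            (
                get(r, "chrom"),
                int(get(r, "start")),
                int(get(r, "end")),
                str(get(r, "name", f"region_{i + 1}")),
                score,
            )
        )
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4g}\n")


# ---------------------------------------------------------------------------
# expression counts + sample sheet
# ---------------------------------------------------------------------------

def read_counts_matrix(
    counts_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    """Read a counts TSV (first column gene_id, optional 'length' column)
    together with a sample sheet TSV (sample_id, tissue, replicate)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"NA cells in counts matrix {counts_path}")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(float)
    vals = df.values
    if not np.allclose(vals, np.round(vals)):
        raise FormatError(f"non-integer counts in {counts_path}")
    counts = df.astype(np.int64)
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tissue", "replicate"}
    if not required.issubset(samples.columns):
        raise FormatError(
            f"sample sheet {sample_sheet_path} needs columns {sorted(required)}"
        )
    return ExpressionMatrix(counts=counts, samples=samples, lengths=lengths)


def write_counts_matrix(
    matrix: ExpressionMatrix, counts_path: str | Path, sample_sheet_path: str | Path
) -> None:
    out = matrix.counts.copy()
    if matrix.lengths is not None:
        out.insert(0, "length", matrix.lengths.astype(int))
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(sample_sheet_path, sep="\t", index=False)
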