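"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
- GFF3 gene models (1-based inclusive on disk, converted to 0-based half-open)
- BED3/BED5 peak calls
- BEDPE paired-end tags and loops (col 7 = PET count; loops add col 8 = source,
  col 9 = peak support)
- TSV methylation table: chrom, pos, context, n_meth, n_total
- TSV expression matrix: genes x tissues, FPKM
- TSV association tables: eQTL (snp_chrom, snp_pos, gene_id, kind) and
  GWAS/QTL SNPs (chrom, pos, trait)

Every reader/writer pair round-trips losslessly on valid files, up to the
canonical anchor ordering of BEDPE records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    EqtlAssociation,
    GeneModel,
    GenomicInterval,
    GwasSnp,
    Loop,
    MethylationCall,
    Peak,
    Pet,
)


class ParseError(ValueError):
    """Raised for malformed input lines, carrying the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class ExpressionMatrix:
    """FPKM expression values for genes (rows) across tissues (columns)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.duplicated().any():
            raise ValueError("duplicate tissue ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-numeric/NaN values")
        if (arr < 0).any():
            raise ValueError("FPKM values must be >= 0")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, feature_types: Sequence[str] = ("gene",)) -> list[GeneModel]:
    """Parse gene features from a GFF3 file into 0-based half-open models."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {strand!r}")
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if not gene_id:
                raise ParseError(path, lineno, "missing ID attribute")
            if end_i < start_i:
                raise ParseError(path, lineno, "end < start")
            # the only 1-based -> 0-based shift in the codebase
            body = GenomicInterval(chrom, start_i - 1, end_i, strand)
            genes.append(GeneModel(gene_id, body))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.body.chrom}\t.\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.body.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, mark: str = "") -> list[Peak]:
    """Read BED3+ peaks; column 4 = name, column 5 = intensity (default 0)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ParseError(path, lineno, f"end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            intensity = float(fields[4]) if len(fields) > 4 else 0.0
            peaks.append(Peak(GenomicInterval(chrom, start, end), intensity, mark, name))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            fh.write(
                f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t{name}\t"
                f"{p.intensity:g}\n"
            )


def write_intervals_bed(intervals: Sequence[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe_pets(path) -> list[Pet]:
    """Read PETs from BEDPE. Optional column 7 is a replication count.

    Same-chromosome records whose two tags overlap are kept but flagged, so
    downstream filters can decide; they are never silently dropped.
    """
    pets: list[Pet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(path, lineno, "expected >= 6 BEDPE fields")
            tag_a = GenomicInterval(f[0], int(f[1]), int(f[2]))
            tag_b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            count = int(f[6]) if len(f) > 6 and f[6] not in (".", "") else 1
            flagged = tag_a.overlaps(tag_b)
            pets.append(Pet(tag_a, tag_b, count=count, flagged_overlap=flagged))
    return pets


def write_bedpe_pets(pets: Sequence[Pet], path) -> None:
    with open(path, "w") as fh:
        for p in pets:
            fh.write(
                f"{p.tagA.chrom}\t{p.tagA.start}\t{p.tagA.end}\t"
                f"{p.tagB.chrom}\t{p.tagB.start}\t{p.tagB.end}\t{p.count}\n"
            )


def read_bedpe_loops(path) -> list[Loop]:
    """Read loops from BEDPE: col 7 = pet_count, col 8 = source, col 9 = support."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(path, lineno, "expected >= 6 BEDPE fields")
            loops.append(
                Loop(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    pet_count=int(f[6]) if len(f) > 6 else 1,
                    source="" if len(f) <= 7 or f[7] == "." else f[7],
                    peak_support="" if len(f) <= 8 or f[8] == "." else f[8],
                    label="" if len(f) <= 9 or f[9] == "." else f[9],
                )
            )
    return loops


def write_bedpe_loops(loops: Sequence[Loop], path) -> None:
    with open(path, "w") as fh:
        for lo in loops:
            fh.write(
                f"{lo.anchorA.chrom}\t{lo.anchorA.start}\t{lo.anchorA.end}\t"
                f"{lo.anchorB.chrom}\t{lo.anchorB.start}\t{lo.anchorB.end}\t"
                f"{lo.pet_count}\t{lo.source or '.'}\t{lo.peak_support or '.'}\t"
                f"{lo.label or '.'}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

METHYLATION_COLUMNS = ["chrom", "pos", "context", "n_meth", "n_total"]


def read_methylation_table(path) -> list[MethylationCall]:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(METHYLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing methylation columns {sorted(missing)}")
    if (df["n_meth"] > df["n_total"]).any():
        bad = df.index[df["n_meth"] > df["n_total"]][0]
        raise ValueError(f"{path}: n_meth > n_total at data row {bad}")
    return [
        MethylationCall(r.chrom, int(r.pos), r.context, int(r.n_meth), int(r.n_total))
        for r in df.itertuples(index=False)
    ]


def write_methylation_table(calls: Sequence[MethylationCall], path) -> None:
    df = pd.DataFrame(
        [(c.chrom, c.pos, c.context, c.n_meth, c.n_total) for c in calls],
        columns=METHYLATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def methylation_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    """Columnar view of methylation calls used by vectorized callers."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": np.fromiter((c.pos for c in calls), dtype=np.int64, count=len(calls)),
            "context": [c.context for c in calls],
            "n_meth": np.fromiter((c.n_meth for c in calls), dtype=np.int64, count=len(calls)),
            "n_total": np.fromiter((c.n_total for c in calls), dtype=np.int64, count=len(calls)),
        }
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric FPKM value ({exc})") from None
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


EQTL_COLUMNS = ["snp_chrom", "snp_pos", "gene_id", "kind"]


def read_association_table(path) -> list[EqtlAssociation]:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"gene_id": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing association columns {sorted(missing)}")
    if df["gene_id"].isna().any() or (df["gene_id"].str.len() == 0).any():
        raise ValueError(f"{path}: association row with missing gene id")
    return [
        EqtlAssociation(r.snp_chrom, int(r.snp_pos), r.gene_id, r.kind)
        for r in df.itertuples(index=False)
    ]


def write_association_table(eqtls: Sequence[EqtlAssociation], path) -> None:
    pd.DataFrame(
        [(e.snp_chrom, e.snp_pos, e.gene_id, e.kind) for e in eqtls],
        columns=EQTL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gwas_table(path) -> list[GwasSnp]:
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing GWAS column {col!r}")
    trait = df["trait"] if "trait" in df.columns else [""] * len(df)
    return [
        GwasSnp(c, int(p), str(t))
        for c, p, t in zip(df["chrom"], df["pos"], trait)
    ]


def write_gwas_table(snps: Sequence[GwasSnp], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.trait) for s in snps], columns=["chrom", "pos", "trait"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
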