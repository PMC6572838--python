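"""Core genomic data model shared by every stage of the pipeline.

All coordinates inside the package are 0-based half-open (BED convention).
GFF3 input/output is the single place where a 1-based inclusive shift is
applied. Intervals are canonically ordered by (chrom, start, end) with a
lexicographic chromosome tie-break, which makes deduplication and loop-anchor
normalization deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

CHIP_MARKS = (
    "H3K4me3",
    "H3K4me1",
    "H3K27ac",
    "H3K27me3",
    "RNAPII",
    "MNase_heavy",
    "MNase_light",
)

METH_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        """True when the two intervals share at least ``min_overlap`` bp."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def unstranded(self) -> "GenomicInterval":
        return replace(self, strand=".") if self.strand != "." else self


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived transcription start site."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self):
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or - to define a TSS"
            )

    @property
    def tss(self) -> int:
        """TSS coordinate: leftmost base for + genes, rightmost for - genes."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def strand(self) -> str:
        return self.body.strand


@dataclass(frozen=True)
class Peak:
    """A ChIP/MNase peak call with a nonnegative intensity score."""

    region: GenomicInterval
    intensity: float = 0.0
    mark: str = ""
    name: str = ""

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class MethylationCall:
    """Per-cytosine bisulfite call: methylated reads out of total reads."""

    chrom: str
    pos: int
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.context not in METH_CONTEXTS:
            raise ValueError(f"context must be one of {METH_CONTEXTS}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError("require 0 <= n_meth <= n_total")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    @property
    def level(self) -> float:
        return self.n_meth / self.n_total


def _canonical_pair(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[GenomicInterval, GenomicInterval]:
    return (a, b) if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end) else (b, a)


@dataclass(frozen=True)
class Pet:
    """A paired-end tag: the two sequenced ends of one ligation product.

    Tags are stored in canonical order (anchorA <= anchorB by chrom/start).
    ``category`` is filled in by :func:`chialoop.loops.categorize_pets`.
    """

    tagA: GenomicInterval
    tagB: GenomicInterval
    count: int = 1
    category: str = ""
    flagged_overlap: bool = False

    def __post_init__(self):
        a, b = _canonical_pair(self.tagA, self.tagB)
        object.__setattr__(self, "tagA", a)
        object.__setattr__(self, "tagB", b)
        if self.count < 1:
            raise ValueError("PET count must be >= 1")

    @property
    def intrachromosomal(self) -> bool:
        return self.tagA.chrom == self.tagB.chrom

    @property
    def span(self) -> int | None:
        """Distance between tag midpoints; None across chromosomes."""
        if not self.intrachromosomal:
            return None
        return abs(self.tagB.midpoint - self.tagA.midpoint)


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two anchors, supported by >=1 PETs."""

    anchorA: GenomicInterval
    anchorB: GenomicInterval
    pet_count: int = 1
    source: str = ""
    peak_support: str = ""
    label: str = ""

    def __post_init__(self):
        a, b = _canonical_pair(self.anchorA, self.anchorB)
        object.__setattr__(self, "anchorA", a)
        object.__setattr__(self, "anchorB", b)
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")

    @property
    def intrachromosomal(self) -> bool:
        return self.anchorA.chrom == self.anchorB.chrom

    @property
    def span(self) -> int | None:
        if not self.intrachromosomal:
            return None
        return abs(self.anchorB.midpoint - self.anchorA.midpoint)


@dataclass(frozen=True)
class EqtlAssociation:
    """Top-SNP to expression-trait gene association."""

    snp_chrom: str
    snp_pos: int
    gene_id: str
    kind: str = "cis"

    def __post_init__(self):
        if self.snp_pos < 0:
            raise ValueError("snp_pos must be >= 0")
        if self.kind not in ("cis", "trans"):
            raise ValueError("kind must be 'cis' or 'trans'")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")


@dataclass(frozen=True)
class GwasSnp:
    chrom: str
    pos: int
    trait: str = ""

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


class GenomeIndex:
    """Per-chromosome interval tree over arbitrary payload objects.

    Thin wrapper around :mod:`intervaltree` used for every >=1 bp overlap
    query in the pipeline.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)

    def query(self, iv: GenomicInterval) -> list[object]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def query_point(self, chrom: str, pos: int) -> list[object]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def any_overlap(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return False
        for hit in tree.overlap(iv.start, iv.end):
            if min(hit.end, iv.end) - max(hit.begin, iv.start) >= min_overlap:
                return True
        return False

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "GenomeIndex":
        return cls((iv, iv) for iv in intervals)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or book-ended ranges are merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
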