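"""Seed-reproducible synthetic input bundles with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: non-overlapping genes on one or more chromosomes, ChIP peaks at
active promoters, hypomethylated blocks (planted LUMRs), MNase-hypersensitive
distal elements supported by LUMRs, chromatin loops expanded into >=3
supporting PETs plus uniform noise PETs, an FPKM expression matrix where
looped gene pairs share a latent tissue factor (planted Pearson correlation),
and eQTL/GWAS tables with a configured fraction of loop-linked records.

Every planted object is recorded in a :class:`GroundTruthManifest`, so the
full pipeline can be scored for precision and recall against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
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
    Peak,
    Pet,
)
from . import io as cio
from .elements import call_promoter_regions


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a single 10-Mb chromosome with 300 genes, 50 planted
    loops spanning 10-100 kb, 20 planted LUMRs, ~1000 uniform noise PETs,
    79 expression tissues and a planted looped-pair correlation of 0.6.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 10_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2000, 5000)
    min_gene_gap: int = 6000
    promoter_upstream: int = 2000
    promoter_downstream: int = 1500
    peaked_gene_fraction: float = 0.8

    n_planted_loops: int = 50
    loop_span_range: tuple[int, int] = (10_000, 100_000)
    ppi_fraction: float = 0.6
    pdi_fraction: float = 0.4
    anchor_width: int = 1000
    pets_per_loop: tuple[int, int] = (5, 11)
    pet_jitter: int = 150
    tag_width: int = 100
    noise_pet_fraction: float = 2.5

    n_planted_lumrs: int = 20
    meth_bin_size: int = 200
    lumr_width_bins: tuple[int, int] = (3, 6)
    background_methylation: dict = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.6, "CHH": 0.05}
    )
    lumr_methylation: dict = field(
        default_factory=lambda: {"CG": 0.02, "CHG": 0.01, "CHH": 0.01}
    )
    site_spacing: int = 10
    read_depth: int = 20
    n_decoy_heavy_peaks: int = 9
    n_orphan_elements: int = 5  # LUMR-supported elements without any loop

    anchor_intensity_boost: float = 2.0  # anchor peaks are brighter than the rest

    n_tissues: int = 79
    coexpression_rho: float = 0.6
    background_rho: float = 0.0

    n_eqtls: int = 30
    eqtl_loop_link_fraction: float = 0.4
    n_gwas_snps: int = 15
    gwas_element_link_fraction: float = 0.6
    gwas_window: int = 200_000

    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "n_genes", "n_planted_loops", "n_planted_lumrs",
                     "n_eqtls", "n_gwas_snps", "n_tissues"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ppi_fraction", "pdi_fraction", "eqtl_loop_link_fraction",
                     "gwas_element_link_fraction", "peaked_gene_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ppi_fraction + self.pdi_fraction > 1 + 1e-9:
            raise ValueError("ppi_fraction + pdi_fraction must be <= 1")
        if not 0 <= self.background_rho <= self.coexpression_rho <= 1:
            raise ValueError("require 0 <= background_rho <= coexpression_rho <= 1")
        lo, hi = self.loop_span_range
        if not (0 < lo <= hi < self.chromosome_length):
            raise ValueError("loop_span_range must lie within (0, chromosome_length)")
        if self.noise_pet_fraction < 0:
            raise ValueError("noise_pet_fraction must be >= 0")


@dataclass
class GroundTruthManifest:
    """Planted truth for scoring pipeline output."""

    loops: list[dict] = field(default_factory=list)
    lumrs: list[dict] = field(default_factory=list)
    distal_elements: list[dict] = field(default_factory=list)
    coexpressed_pairs: list[dict] = field(default_factory=list)
    eqtls: list[dict] = field(default_factory=list)
    gwas_snps: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    h3k4me3_peaks: list[Peak]
    rnapii_peaks: list[Peak]
    mnase_heavy: list[Peak]
    mnase_light: list[Peak]
    methylation: pd.DataFrame
    pets: list[Pet]
    expression: cio.ExpressionMatrix
    eqtls: list[EqtlAssociation]
    gwas_snps: list[GwasSnp]
    manifest: GroundTruthManifest

    def write(self, outdir) -> dict[str, str]:
        """Write the bundle as plain-text files; returns the path map."""
        out = cio.ensure_dir(outdir)
        paths = {
            "genes": out / "genes.gff3",
            "h3k4me3": out / "h3k4me3_peaks.bed",
            "rnapii": out / "rnapii_peaks.bed",
            "mnase_heavy": out / "mnase_heavy_peaks.bed",
            "mnase_light": out / "mnase_light_peaks.bed",
            "methylation": out / "methylation.tsv",
            "pets": out / "pets.bedpe",
            "expression": out / "expression_fpkm.tsv",
            "eqtls": out / "eqtl_associations.tsv",
            "gwas": out / "gwas_snps.tsv",
            "manifest": out / "manifest.json",
            "chrom_sizes": out / "chrom_sizes.tsv",
        }
        cio.write_gff3(self.genes, paths["genes"])
        cio.write_bed(self.h3k4me3_peaks, paths["h3k4me3"])
        cio.write_bed(self.rnapii_peaks, paths["rnapii"])
        cio.write_bed(self.mnase_heavy, paths["mnase_heavy"])
        cio.write_bed(self.mnase_light, paths["mnase_light"])
        self.methylation.to_csv(paths["methylation"], sep="\t", index=False)
        cio.write_bedpe_pets(self.pets, paths["pets"])
        cio.write_expression_matrix(self.expression, paths["expression"])
        cio.write_association_table(self.eqtls, paths["eqtls"])
        cio.write_gwas_table(self.gwas_snps, paths["gwas"])
        self.manifest.to_json(paths["manifest"])
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, ln in sorted(self.chrom_lengths.items()):
                fh.write(f"{chrom}\t{ln}\n")
        return {k: str(v) for k, v in paths.items()}


def _iv_dict(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end}


class _Occupancy:
    """Sorted per-chromosome interval bookkeeping for rejection sampling."""

    def __init__(self):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def clashes(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):  # lists stay short (<1k)
            if start - margin < e and s < end + margin:
                return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def expand_loop_to_pets(
    loop: Loop,
    n_pets: int,
    anchor_jitter: int,
    rng: np.random.Generator | None = None,
    tag_width: int = 100,
) -> list[Pet]:
    """Expand one loop into supporting PETs with jittered tag placement.

    Each tag is ``tag_width`` wide, centered at the anchor midpoint plus a
    uniform integer offset in [-anchor_jitter, anchor_jitter], and always
    falls within its (jittered) anchor region.
    """
    if n_pets < 1:
        raise ValueError("n_pets must be >= 1")
    for anchor in (loop.anchorA, loop.anchorB):
        if 2 * anchor_jitter + tag_width > anchor.width:
            raise ValueError(
                f"anchor_jitter {anchor_jitter} too large for anchor width {anchor.width}"
            )
    rng = rng or np.random.default_rng(0)
    pets = []
    for _ in range(n_pets):
        tags = []
        for anchor in (loop.anchorA, loop.anchorB):
            off = int(rng.integers(-anchor_jitter, anchor_jitter + 1)) if anchor_jitter else 0
            c = anchor.midpoint + off
            tags.append(GenomicInterval(anchor.chrom, c - tag_width // 2, c - tag_width // 2 + tag_width))
        pets.append(Pet(tags[0], tags[1]))
    return pets


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete input bundle plus its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}
    manifest = GroundTruthManifest()

    genes = _place_genes(config, rng, chroms)
    gene_by_id = {g.gene_id: g for g in genes}
    promoters = call_promoter_regions(
        genes, config.promoter_upstream, config.promoter_downstream, chrom_lengths
    )

    # peaks at active promoters ([tss-500, tss+500))
    n_peaked = int(round(config.peaked_gene_fraction * len(genes)))
    peaked_ids = sorted(
        rng.choice([g.gene_id for g in genes], size=n_peaked, replace=False)
    )
    peaked_set = set(peaked_ids)
    h3k4me3, rnapii = [], []
    for gid in peaked_ids:
        g = gene_by_id[gid]
        iv = GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
        h3k4me3.append(Peak(iv, float(np.round(rng.lognormal(2.5, 0.5), 3)), "H3K4me3", f"k4_{gid}"))
        rnapii.append(Peak(iv, float(np.round(rng.lognormal(2.3, 0.5), 3)), "RNAPII", f"pol_{gid}"))

    # ---- planted loops -------------------------------------------------
    n_ppi = int(round(config.n_planted_loops * config.ppi_fraction))
    n_pdi = int(round(config.n_planted_loops * config.pdi_fraction))
    n_pdi = min(n_pdi, config.n_planted_loops - n_ppi)

    # loop-linked eQTLs need a hub gene with two loop partners: one becomes
    # the associated (looped) etrait, the other the eQTL-interacting gene
    n_triplets = min(
        int(round(config.eqtl_loop_link_fraction * config.n_eqtls)), n_ppi // 2
    )
    groups = _pick_ppi_groups(
        config, rng, genes, peaked_set, n_triplets, n_ppi - 2 * n_triplets
    )
    ppi_pairs: list[tuple[str, str]] = []  # looped promoter pairs (hub, partner)
    loops: list[Loop] = []
    loop_records: list[dict] = []
    for group in groups:
        hub = group[0]
        for partner in group[1:]:
            a = _tss_anchor(gene_by_id[hub], config.anchor_width)
            b = _tss_anchor(gene_by_id[partner], config.anchor_width)
            lo = Loop(a, b, pet_count=1, source="planted", label="PPI")
            loops.append(lo)
            ppi_pairs.append((hub, partner))
            loop_records.append(
                {"anchorA": _iv_dict(lo.anchorA), "anchorB": _iv_dict(lo.anchorB),
                 "label": "PPI", "genes": sorted((hub, partner)), "element_id": None}
            )

    occupied = _Occupancy()
    for g in genes:
        occupied.add(g.chrom, g.body.start, g.body.end)

    ppi_gene_set = {g for grp in groups for g in grp}
    elements, element_targets = _place_distal_elements(
        config, rng, genes, peaked_set, occupied, n_pdi, exclude_genes=ppi_gene_set
    )
    pdi_gene_set: set[str] = set()
    for elem_id, region, targets in elements:
        for gid in targets:
            b = _tss_anchor(gene_by_id[gid], config.anchor_width)
            lo = Loop(region, b, pet_count=1, source="planted", label="PDI")
            loops.append(lo)
            pdi_gene_set.add(gid)
            loop_records.append(
                {"anchorA": _iv_dict(lo.anchorA), "anchorB": _iv_dict(lo.anchorB),
                 "label": "PDI", "genes": [gid], "element_id": elem_id}
            )
        manifest.distal_elements.append(
            {"element_id": elem_id, "region": _iv_dict(region), "target_genes": sorted(targets)}
        )
    manifest.loops = loop_records

    # anchor peaks carry higher ChIP intensity than non-anchor peaks
    anchor_genes = ppi_gene_set | pdi_gene_set
    boost = config.anchor_intensity_boost

    def _boosted(peaks, prefix):
        out_peaks = []
        for pk in peaks:
            gid = pk.name.split("_", 1)[1]
            if gid in anchor_genes and boost != 1.0:
                pk = Peak(pk.region, round(pk.intensity * boost, 3), pk.mark, pk.name)
            out_peaks.append(pk)
        return out_peaks

    h3k4me3 = _boosted(h3k4me3, "k4")
    rnapii = _boosted(rnapii, "pol")

    # ---- LUMR blocks ----------------------------------------------------
    element_regions = [region for _, region, _ in elements]
    lumr_blocks = _place_lumrs(config, rng, element_regions, occupied, chrom_lengths)
    manifest.lumrs = [_iv_dict(b) for b in lumr_blocks]
    for b in lumr_blocks:  # keep decoy peaks clear of every planted LUMR
        occupied.add(b.chrom, b.start, b.end)

    # ---- decoy MNase peaks ----------------------------------------------
    heavy, light = _decoy_mnase_peaks(config, rng, genes, occupied, chrom_lengths)
    for i, (_, region, _) in enumerate(elements):
        heavy.append(Peak(region, float(np.round(rng.lognormal(2.0, 0.4), 3)),
                          "MNase_heavy", f"de_{i:03d}"))
    heavy.sort(key=lambda p: (p.region.chrom, p.region.start))
    light.sort(key=lambda p: (p.region.chrom, p.region.start))

    # ---- methylation ----------------------------------------------------
    methylation = _simulate_methylation(config, rng, chrom_lengths, lumr_blocks)

    # ---- PETs ------------------------------------------------------------
    pets: list[Pet] = []
    for lo in loops:
        n = int(rng.integers(config.pets_per_loop[0], config.pets_per_loop[1] + 1))
        pets.extend(expand_loop_to_pets(lo, n, config.pet_jitter, rng, config.tag_width))
    n_noise = int(round(config.noise_pet_fraction * len(pets)))
    pets.extend(_noise_pets(config, rng, chroms, n_noise))

    # ---- expression -------------------------------------------------------
    expression = _simulate_expression(
        config, rng, genes, groups, peaked_set, pdi_gene_set
    )
    manifest.coexpressed_pairs = [
        {"gene_a": a, "gene_b": b, "rho": config.coexpression_rho}
        for a, b in (sorted(p) for p in ppi_pairs)
    ]

    # ---- eQTLs -------------------------------------------------------------
    eqtls = _plant_eqtls(config, rng, gene_by_id, groups, n_triplets, peaked_set,
                         pdi_gene_set, manifest)

    # ---- GWAS SNPs ----------------------------------------------------------
    interacting_elements = [e for e in elements if e[2]]
    gwas = _plant_gwas(config, rng, interacting_elements, chrom_lengths, manifest)

    return SyntheticBundle(
        config, chrom_lengths, genes, h3k4me3, rnapii, heavy, light,
        methylation, pets, expression, eqtls, gwas, manifest,
    )


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------


def _place_genes(config, rng, chroms) -> list[GeneModel]:
    occupied = _Occupancy()
    placed: list[tuple[str, int, int, str]] = []
    lo_len, hi_len = config.gene_length_range
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    counts = {c: 0 for c in chroms}
    total = 0
    for chrom in chroms:
        while counts[chrom] < per_chrom and total < config.n_genes:
            for attempt in range(2000):
                length = int(rng.integers(lo_len, hi_len + 1))
                start = int(rng.integers(0, config.chromosome_length - length))
                if not occupied.clashes(chrom, start, start + length, margin=config.min_gene_gap):
                    occupied.add(chrom, start, start + length)
                    strand = "+" if rng.random() < 0.5 else "-"
                    placed.append((chrom, start, start + length, strand))
                    counts[chrom] += 1
                    total += 1
                    break
            else:
                raise RuntimeError(
                    f"cannot place {config.n_genes} non-overlapping genes with "
                    f"gap {config.min_gene_gap} on {len(chroms)} x "
                    f"{config.chromosome_length} bp"
                )
    placed.sort()
    return [
        GeneModel(f"g{i + 1:04d}", GenomicInterval(c, s, e, st))
        for i, (c, s, e, st) in enumerate(placed)
    ]


def _tss_anchor(gene: GeneModel, width: int) -> GenomicInterval:
    half = width // 2
    return GenomicInterval(gene.chrom, max(0, gene.tss - half), gene.tss - half + width)


def _pick_ppi_groups(
    config, rng, genes, peaked_set, n_triplets, n_pairs
) -> list[list[str]]:
    """Disjoint promoter loop groups: the first gene of each group is the hub.

    A triplet plants two loops sharing the hub anchor; a pair plants one.
    All partner TSSs lie within the loop span range of the hub TSS.
    """
    lo, hi = config.loop_span_range
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id in peaked_set:
            by_chrom.setdefault(g.chrom, []).append(g)
    gene_by_id = {g.gene_id: g for g in genes}
    order = list(rng.permutation([g.gene_id for gs in by_chrom.values() for g in gs]))
    groups: list[list[str]] = []
    used: set[str] = set()
    for size in [3] * n_triplets + [2] * n_pairs:
        made = False
        for gid in order:
            if gid in used:
                continue
            g = gene_by_id[gid]
            cands = [
                h for h in by_chrom[g.chrom]
                if h.gene_id not in used and h.gene_id != gid
                and lo <= abs(h.tss - g.tss) <= hi
            ]
            if len(cands) < size - 1:
                continue
            idx = rng.choice(len(cands), size=size - 1, replace=False)
            group = [gid] + [cands[int(i)].gene_id for i in idx]
            groups.append(group)
            used.update(group)
            made = True
            break
        if not made:
            raise RuntimeError(
                f"could not form a {size}-gene promoter loop group within the span range"
            )
    return groups


def _place_distal_elements(
    config, rng, genes, peaked_set, occupied: _Occupancy, n_pdi, exclude_genes
):
    """Place elements in intergenic space and pick loop-span target genes.

    Roughly a quarter of the PDI budget is spent on "multiple" elements that
    loop to two genes each; the rest are single-target elements.
    """
    if n_pdi == 0 and config.n_orphan_elements == 0:
        return [], {}
    n_multi = n_pdi // 4
    n_single = n_pdi - 2 * n_multi
    wanted = [2] * n_multi + [1] * n_single + [0] * config.n_orphan_elements
    lo, hi = config.loop_span_range
    margin = 2600  # gene flank (2 kb) + separation so anchors never merge

    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id in peaked_set and g.gene_id not in exclude_genes:
            gene_by_chrom.setdefault(g.chrom, []).append(g)

    elements = []
    used_targets: set[str] = set()
    for k, n_targets in enumerate(wanted):
        placed = False
        for attempt in range(5000):
            chrom = list(gene_by_chrom)[int(rng.integers(len(gene_by_chrom)))]
            width = int(rng.integers(400, 801))
            start = int(rng.integers(0, config.chromosome_length - width))
            if occupied.clashes(chrom, start, start + width, margin=margin):
                continue
            mid = start + width // 2
            cands = [
                g for g in gene_by_chrom[chrom]
                if g.gene_id not in used_targets and lo <= abs(g.tss - mid) <= hi
            ]
            if len(cands) < n_targets:
                continue
            idx = rng.choice(len(cands), size=n_targets, replace=False)
            targets = [cands[int(i)].gene_id for i in idx]
            used_targets.update(targets)
            region = GenomicInterval(chrom, start, start + width)
            elements.append((f"de_{k:03d}", region, targets))
            occupied.add(chrom, start, start + width)
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a distal element satisfying loop-span targets")
    # rename source ids to match emitted heavy-peak order later
    elements = [(f"de_{i:03d}", r, t) for i, (_, r, t) in enumerate(elements)]
    return elements, {e[0]: e[2] for e in elements}


def _place_lumrs(config, rng, element_regions, occupied: _Occupancy, chrom_lengths):
    """Grid-aligned hypomethylated blocks: one per element, plus extras."""
    bs = config.meth_bin_size
    if config.n_planted_lumrs < len(element_regions):
        raise ValueError(
            f"n_planted_lumrs={config.n_planted_lumrs} is fewer than the "
            f"{len(element_regions)} distal elements that need LUMR support"
        )
    blocks: list[GenomicInterval] = []
    for region in element_regions:
        b0 = (region.start // bs) * bs
        b1 = int(np.ceil(region.end / bs)) * bs
        blocks.append(GenomicInterval(region.chrom, b0, b1))
    chroms = sorted(chrom_lengths)
    lo_b, hi_b = config.lumr_width_bins
    taken = _Occupancy()
    for b in blocks:
        taken.add(b.chrom, b.start, b.end)
    while len(blocks) < config.n_planted_lumrs:
        chrom = chroms[int(rng.integers(len(chroms)))]
        nb = int(rng.integers(lo_b, hi_b + 1))
        start_bin = int(rng.integers(0, chrom_lengths[chrom] // bs - nb))
        s, e = start_bin * bs, (start_bin + nb) * bs
        if taken.clashes(chrom, s, e, margin=2 * bs):
            continue
        blocks.append(GenomicInterval(chrom, s, e))
        taken.add(chrom, s, e)
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def _decoy_mnase_peaks(config, rng, genes, occupied: _Occupancy, chrom_lengths):
    """Heavy peaks that each fail exactly one distal-element filter."""
    heavy, light = [], []
    chroms = sorted(chrom_lengths)
    kinds = ["light_overlap", "near_gene", "no_lumr"] * ((config.n_decoy_heavy_peaks + 2) // 3)
    kinds = kinds[: config.n_decoy_heavy_peaks]
    for k, kind in enumerate(kinds):
        for attempt in range(5000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            width = int(rng.integers(400, 801))
            start = int(rng.integers(0, chrom_lengths[chrom] - width))
            if kind == "near_gene":
                # drop it just inside the 2-kb gene flank
                gs = [g for g in genes if g.chrom == chrom]
                if not gs:
                    continue
                g = gs[int(rng.integers(len(gs)))]
                start = g.body.end + int(rng.integers(200, 1200))
                if start + width > chrom_lengths[chrom]:
                    continue
                if occupied.clashes(chrom, start, start + width, margin=0):
                    continue
            else:
                if occupied.clashes(chrom, start, start + width, margin=2600):
                    continue
            region = GenomicInterval(chrom, start, start + width)
            inten = float(np.round(rng.lognormal(2.0, 0.4), 3))
            heavy.append(Peak(region, inten, "MNase_heavy", f"decoy_{kind}_{k}"))
            if kind == "light_overlap":
                light.append(Peak(region, float(np.round(rng.lognormal(1.5, 0.4), 3)),
                                  "MNase_light", f"light_{k}"))
            occupied.add(chrom, start, start + width)
            break
    return heavy, light


def _simulate_methylation(config, rng, chrom_lengths, lumr_blocks) -> pd.DataFrame:
    """Per-cytosine calls on a regular site grid with planted low blocks."""
    bg = config.background_methylation
    low = config.lumr_methylation
    frames = []
    contexts = np.array(["CG", "CHG", "CHH"])
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos = np.arange(0, length, config.site_spacing, dtype=np.int64)
        pos = pos + rng.integers(0, config.site_spacing, size=len(pos))
        pos = np.minimum(pos, length - 1)
        # interleaved contexts (CG:CHG:CHH = 1:1:2), as in real genomes where
        # all three contexts co-occur at a fine scale
        pattern = np.array([0, 2, 1, 2])
        ctx = contexts[pattern[np.arange(len(pos)) % 4]]
        mean = np.select(
            [ctx == "CG", ctx == "CHG"], [bg["CG"], bg["CHG"]], default=bg["CHH"]
        ).astype(float)
        in_block = np.zeros(len(pos), dtype=bool)
        for b in lumr_blocks:
            if b.chrom == chrom:
                in_block |= (pos >= b.start) & (pos < b.end)
        low_mean = np.select(
            [ctx == "CG", ctx == "CHG"], [low["CG"], low["CHG"]], default=low["CHH"]
        ).astype(float)
        mean = np.where(in_block, low_mean, mean)
        # per-site level: beta around the context mean; planted blocks get a
        # tight concentration so they stay below threshold under sampling
        conc = np.where(in_block, 100.0, 20.0)
        a = np.clip(mean, 1e-3, 1 - 1e-3) * conc
        b_par = conc - a
        level = rng.beta(a, b_par)
        n_total = 1 + rng.poisson(config.read_depth - 1, size=len(pos))
        n_meth = rng.binomial(n_total, level)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "context": ctx,
                 "n_meth": n_meth, "n_total": n_total}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _noise_pets(config, rng, chroms, n_noise) -> list[Pet]:
    out = []
    tw = config.tag_width
    for _ in range(n_noise):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = config.chromosome_length
        span = int(np.exp(rng.uniform(np.log(1000), np.log(length / 10))))
        start = int(rng.integers(0, length - span - tw))
        out.append(
            Pet(
                GenomicInterval(chrom, start, start + tw),
                GenomicInterval(chrom, start + span, start + span + tw),
            )
        )
    return out


def _simulate_expression(config, rng, genes, groups, peaked_set, pdi_gene_set):
    """Latent-factor FPKM matrix with planted looped-group correlation.

    Each gene's latent trajectory across tissues is
    x = sqrt(bg) z0 + sqrt(rho - bg) z_group + sqrt(1 - rho) eps for loop
    group members (shared z_group) and x = sqrt(bg) z0 + sqrt(1 - bg) eps
    otherwise, then FPKM = exp(mu_g + 0.8 x): the pairwise Pearson
    correlation of group members is approximately rho on the log scale.
    """
    n_t = config.n_tissues
    rho, bg = config.coexpression_rho, config.background_rho
    gene_ids = [g.gene_id for g in genes]
    z0 = rng.standard_normal(n_t)
    group_of: dict[str, np.ndarray] = {}
    for group in groups:
        z = rng.standard_normal(n_t)
        for gid in group:
            group_of[gid] = z
    loop_genes = set(group_of) | pdi_gene_set
    rows = []
    for gid in gene_ids:
        eps = rng.standard_normal(n_t)
        if gid in group_of:
            x = np.sqrt(bg) * z0 + np.sqrt(rho - bg) * group_of[gid] + np.sqrt(1 - rho) * eps
        else:
            x = np.sqrt(bg) * z0 + np.sqrt(1 - bg) * eps
        if gid in loop_genes:
            mu = np.log(25.0)
        elif gid in peaked_set:
            mu = np.log(8.0)
        else:
            mu = np.log(2.0)
        rows.append(np.round(np.exp(mu + 0.8 * x), 4))
    df = pd.DataFrame(
        np.vstack(rows), index=gene_ids,
        columns=[f"tissue_{i + 1:02d}" for i in range(n_t)],
    )
    return cio.ExpressionMatrix(df)


def _plant_eqtls(config, rng, gene_by_id, groups, n_triplets, peaked_set,
                 pdi_gene_set, manifest):
    """SNP at the hub TSS of each triplet: the first partner is the looped
    etrait gene, the second is a non-associated eQTL-interacting gene."""
    eqtls: list[EqtlAssociation] = []
    for group in groups[:n_triplets]:
        hub, looped_gene, interacting = group
        g = gene_by_id[hub]
        snp_pos = g.tss  # inside the hub anchor and promoter
        eqtls.append(EqtlAssociation(g.chrom, snp_pos, looped_gene, "cis"))
        manifest.eqtls.append(
            {"snp_chrom": g.chrom, "snp_pos": snp_pos, "gene_id": looped_gene,
             "kind": "cis", "loop_linked": True, "interacting_gene": interacting}
        )
    n_linked = len(eqtls)
    loop_genes = {g for grp in groups for g in grp} | pdi_gene_set
    free = sorted(gid for gid in peaked_set if gid not in loop_genes)
    n_free = config.n_eqtls - n_linked
    if n_free > len(free):
        raise RuntimeError("not enough loop-free genes for unlinked eQTLs")
    pick = rng.choice(len(free), size=n_free, replace=False)
    for i in pick:
        gid = free[int(i)]
        g = gene_by_id[gid]
        eqtls.append(EqtlAssociation(g.chrom, g.tss, gid, "cis"))
        manifest.eqtls.append(
            {"snp_chrom": g.chrom, "snp_pos": g.tss, "gene_id": gid, "kind": "cis",
             "loop_linked": False, "interacting_gene": None}
        )
    return eqtls


def _plant_gwas(config, rng, elements, chrom_lengths, manifest):
    """GWAS SNPs: a fraction placed near interacting elements, rest uniform."""
    gwas: list[GwasSnp] = []
    n_linked = int(round(config.gwas_element_link_fraction * config.n_gwas_snps))
    n_linked = min(n_linked, len(elements))
    half = config.gwas_window // 2
    chroms = sorted(chrom_lengths)
    order = rng.permutation(len(elements))
    for k, idx in enumerate(order[:n_linked]):
        _, region, _ = elements[int(idx)]
        off = int(rng.integers(-half // 2, half // 2))
        pos = int(np.clip(region.midpoint + off, 0, chrom_lengths[region.chrom] - 1))
        gwas.append(GwasSnp(region.chrom, pos, f"trait_{k}"))
        manifest.gwas_snps.append(
            {"chrom": region.chrom, "pos": pos, "near_element": elements[int(idx)][0]}
        )
    for k in range(config.n_gwas_snps - n_linked):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, chrom_lengths[chrom]))
        gwas.append(GwasSnp(chrom, pos, f"trait_bg_{k}"))
        manifest.gwas_snps.append({"chrom": chrom, "pos": pos, "near_element": None})
    return gwas
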