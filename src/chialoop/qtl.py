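"""eQTL / GWAS integration with chromatin loops.

Links top eQTL SNPs to their expression-trait genes through loop anchors
(4-kb SNP window vs promoter-bearing anchor), classifies genes relative to
eQTLs, and tests enrichment against two permutation nulls: loops re-placed
uniformly on their own chromosome with spans and anchor widths preserved,
and length-matched random regions for the GWAS window scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EqtlAssociation, GeneModel, GenomeIndex, GenomicInterval, GwasSnp, Loop
from .elements import DistalElement, PromoterRegion
from .io import ExpressionMatrix
from .coexpression import pair_correlations

SNP_CATEGORIES = ("promoter_proximal", "distal_element", "gene_body", "intergenic")


def annotate_snps(
    snps: Sequence[tuple[str, int]],
    promoters: Sequence[PromoterRegion],
    distal_elements: Sequence[DistalElement],
    genes: Sequence[GeneModel],
) -> tuple[list[str], dict[str, int]]:
    """Assign each SNP to exactly one genomic category.

    Precedence: promoter_proximal > distal_element > gene_body > intergenic,
    so the assignment is a total partition of the SNP set.
    """
    prom_idx = GenomeIndex()
    for p in promoters:
        prom_idx.add(p.region, p.gene_id)
    de_idx = GenomeIndex()
    for d in distal_elements:
        de_idx.add(d.region, d.source_peak_id)
    gene_idx = GenomeIndex()
    for g in genes:
        gene_idx.add(g.body, g.gene_id)

    labels: list[str] = []
    for chrom, pos in snps:
        if prom_idx.query_point(chrom, pos):
            labels.append("promoter_proximal")
        elif de_idx.query_point(chrom, pos):
            labels.append("distal_element")
        elif gene_idx.query_point(chrom, pos):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    counts = {c: labels.count(c) for c in SNP_CATEGORIES}
    return labels, counts


def snp_window(chrom: str, pos: int, window: int) -> GenomicInterval:
    """Half-open window of total width ``window`` centered on the SNP."""
    half = window // 2
    return GenomicInterval(chrom, max(0, pos - half), pos + half)


@dataclass(frozen=True)
class LoopedEqtlPair:
    eqtl: EqtlAssociation
    loop: Loop


def _count_looped(
    eqtls: Sequence[EqtlAssociation],
    loops: Sequence[Loop],
    promoters_by_gene: Mapping[str, GenomicInterval],
    window: int,
    cis_only_same_chrom: bool = True,
) -> list[LoopedEqtlPair]:
    anchor_idx = GenomeIndex()
    for lo in loops:
        anchor_idx.add(lo.anchorA, (lo, "A"))
        anchor_idx.add(lo.anchorB, (lo, "B"))
    out: list[LoopedEqtlPair] = []
    for e in eqtls:
        prom = promoters_by_gene.get(e.gene_id)
        if prom is None:
            continue
        if cis_only_same_chrom and e.snp_chrom != prom.chrom:
            continue
        win = snp_window(e.snp_chrom, e.snp_pos, window)
        matched = None
        for lo, side in anchor_idx.query(win):
            other = lo.anchorB if side == "A" else lo.anchorA
            if other.overlaps(prom):
                matched = lo
                break
        if matched is not None:
            out.append(LoopedEqtlPair(e, matched))
    return out


def eqtl_loop_overlap(
    eqtls: Sequence[EqtlAssociation],
    loops: Sequence[Loop],
    promoters: Sequence[PromoterRegion],
    snp_window_bp: int = 4000,
    cis_only_same_chrom: bool = True,
) -> list[LoopedEqtlPair]:
    """eQTL-etrait pairs spanned by a loop.

    A pair counts as looped when one anchor overlaps the window centered on
    the top SNP and the other anchor overlaps the etrait gene's promoter
    region. Trans associations whose SNP and gene sit on different
    chromosomes are skipped unless ``cis_only_same_chrom`` is disabled.
    """
    proms = {p.gene_id: p.region for p in promoters}
    return _count_looped(eqtls, loops, proms, snp_window_bp, cis_only_same_chrom)


EQTL_GENE = "eqtl_gene"
LOOPED_GENE = "looped_gene"
EQTL_INTERACTING_GENE = "eqtl_interacting_gene"
RANDOM_GENE = "random_gene"


@dataclass
class EqtlGeneCalls:
    categories: dict[str, str]
    interacting_links: list[tuple[EqtlAssociation, str]]  # (eqtl, interacting gene)
    random_links: list[tuple[EqtlAssociation, str]]


def classify_eqtl_genes(
    eqtls: Sequence[EqtlAssociation],
    looped_pairs: Sequence[LoopedEqtlPair],
    loops: Sequence[Loop],
    promoters: Sequence[PromoterRegion],
    genes: Sequence[GeneModel],
    snp_window_bp: int = 4000,
    seed: int = 0,
    distance_tolerance: float = 0.5,
) -> EqtlGeneCalls:
    """Classify genes relative to eQTLs and draw distance-matched random genes.

    eqtl_gene: eQTL-associated, no loop to its SNP. looped_gene: associated
    and looped. eqtl_interacting_gene: not associated, but its promoter is
    joined to an eQTL SNP window by a loop. For every interacting link a
    random control gene is drawn from non-associated, non-looped genes at a
    matched TSS-to-SNP distance (within +/- ``distance_tolerance`` of the
    interacting gene's distance; nearest-distance fallback).
    """
    rng = np.random.default_rng(seed)
    associated = {e.gene_id for e in eqtls}
    looped_genes = {p.eqtl.gene_id for p in looped_pairs}

    prom_idx = GenomeIndex()
    for p in promoters:
        prom_idx.add(p.region, p.gene_id)
    anchor_idx = GenomeIndex()
    for lo in loops:
        anchor_idx.add(lo.anchorA, (lo, "A"))
        anchor_idx.add(lo.anchorB, (lo, "B"))

    categories: dict[str, str] = {}
    for gid in associated:
        categories[gid] = LOOPED_GENE if gid in looped_genes else EQTL_GENE

    tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    interacting_links: list[tuple[EqtlAssociation, str]] = []
    interacting: set[str] = set()
    for e in eqtls:
        win = snp_window(e.snp_chrom, e.snp_pos, snp_window_bp)
        for lo, side in anchor_idx.query(win):
            other = lo.anchorB if side == "A" else lo.anchorA
            for gid in prom_idx.query(other):
                if gid not in associated:
                    interacting.add(gid)
                    interacting_links.append((e, gid))
    for gid in interacting:
        categories[gid] = EQTL_INTERACTING_GENE

    # distance-matched random controls
    pool = [
        g for g in genes
        if g.gene_id not in associated and g.gene_id not in interacting
    ]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in pool:
        by_chrom.setdefault(g.chrom, []).append(g)
    random_links: list[tuple[EqtlAssociation, str]] = []
    for e, gid in interacting_links:
        chrom, t = tss[gid]
        d = abs(t - e.snp_pos)
        cands = by_chrom.get(e.snp_chrom, [])
        if not cands:
            continue
        dists = np.array([abs(g.tss - e.snp_pos) for g in cands], dtype=float)
        ok = np.where(np.abs(dists - d) <= distance_tolerance * max(d, 1))[0]
        if ok.size:
            pick = cands[int(ok[rng.integers(ok.size)])]
        else:
            pick = cands[int(np.argmin(np.abs(dists - d)))]
        categories.setdefault(pick.gene_id, RANDOM_GENE)
        random_links.append((e, pick.gene_id))
    return EqtlGeneCalls(categories, interacting_links, random_links)


@dataclass
class EnrichmentResult:
    observed: float
    null_values: np.ndarray
    empirical_p: float
    t_p: float
    effect: float

    @property
    def reps(self) -> int:
        return len(self.null_values)


def _add_one_p(null_values: np.ndarray, observed: float) -> float:
    return float((1 + (null_values >= observed).sum()) / (len(null_values) + 1))


def shuffle_loops(
    loops: Sequence[Loop], chrom_lengths: Mapping[str, int], rng: np.random.Generator
) -> list[Loop]:
    """Re-place each loop uniformly on its own chromosome.

    Anchor widths and the anchor-to-anchor offset (hence the span) are
    preserved exactly; placements that would run off the chromosome are
    impossible by construction of the sampling range.
    """
    out = []
    for lo in loops:
        if not lo.intrachromosomal:
            out.append(lo)
            continue
        chrom = lo.anchorA.chrom
        length = chrom_lengths[chrom]
        extent = lo.anchorB.end - lo.anchorA.start
        if extent >= length:
            raise ValueError(
                f"loop extent {extent} exceeds chromosome {chrom} length {length}"
            )
        offset_b = lo.anchorB.start - lo.anchorA.start
        new_start = int(rng.integers(0, length - extent + 1))
        out.append(
            Loop(
                GenomicInterval(chrom, new_start, new_start + lo.anchorA.width),
                GenomicInterval(chrom, new_start + offset_b, new_start + offset_b + lo.anchorB.width),
                pet_count=lo.pet_count,
                source=lo.source,
                peak_support=lo.peak_support,
            )
        )
    return out


def simulate_loops_null(
    loops: Sequence[Loop],
    chrom_lengths: Mapping[str, int],
    eqtls: Sequence[EqtlAssociation],
    promoters: Sequence[PromoterRegion],
    snp_window_bp: int = 4000,
    reps: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of looped eQTL-gene pairs over a shuffled-loop null.

    Each replicate re-places every intra-chromosomal loop uniformly on its
    chromosome (spans and anchor widths preserved) and recounts looped
    eQTL-etrait pairs. Empirical p uses the add-one estimator.
    """
    rng = np.random.default_rng(seed)
    proms = {p.gene_id: p.region for p in promoters}
    intra = [lo for lo in loops if lo.intrachromosomal]
    observed = len(_count_looped(eqtls, intra, proms, snp_window_bp))
    null_counts = np.empty(reps, dtype=float)
    for r in range(reps):
        shuffled = shuffle_loops(intra, chrom_lengths, rng)
        null_counts[r] = len(_count_looped(eqtls, shuffled, proms, snp_window_bp))
    t_p = float(stats.ttest_1samp(null_counts, observed).pvalue) if reps > 1 else float("nan")
    mean_null = null_counts.mean()
    effect = float(observed / mean_null) if mean_null > 0 else float("inf")
    return EnrichmentResult(observed, null_counts, _add_one_p(null_counts, observed), t_p, effect)


def gwas_element_enrichment(
    distal_elements: Sequence[DistalElement],
    interacting_ids: set[str],
    gwas_snps: Sequence[GwasSnp],
    chrom_lengths: Mapping[str, int],
    window: int = 200000,
    random_region_reps: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """GWAS-window hit-rate of interacting vs other elements vs random regions.

    An element hits a SNP when it overlaps (>= 1 bp) the window centered on
    the SNP. Random regions are chromosome- and length-matched to the
    interacting elements and placed uniformly per replicate.
    """
    rng = np.random.default_rng(seed)
    win_idx = GenomeIndex.from_intervals(
        [snp_window(s.chrom, s.pos, window) for s in gwas_snps]
    )

    def hit_rate(regions: Sequence[GenomicInterval]) -> float:
        if not regions:
            return float("nan")
        return sum(win_idx.any_overlap(r) for r in regions) / len(regions)

    inter = [d.region for d in distal_elements if d.source_peak_id in interacting_ids]
    non_inter = [d.region for d in distal_elements if d.source_peak_id not in interacting_ids]
    obs_rate = hit_rate(inter)
    non_inter_rate = hit_rate(non_inter)

    null_rates = np.empty(random_region_reps, dtype=float)
    for r in range(random_region_reps):
        placed = []
        for region in inter:
            length = chrom_lengths[region.chrom]
            start = int(rng.integers(0, max(1, length - region.width + 1)))
            placed.append(GenomicInterval(region.chrom, start, start + region.width))
        null_rates[r] = hit_rate(placed)
    t_p = (
        float(stats.ttest_1samp(null_rates, obs_rate).pvalue)
        if random_region_reps > 1 and np.ptp(null_rates) > 0
        else float("nan")
    )
    mean_null = null_rates.mean()
    result = EnrichmentResult(
        obs_rate, null_rates, _add_one_p(null_rates, obs_rate), t_p,
        float(obs_rate / mean_null) if mean_null > 0 else float("inf"),
    )
    return {
        "interacting": result,
        "non_interacting_rate": non_inter_rate,
        "n_interacting": len(inter),
        "n_non_interacting": len(non_inter),
    }


PAIRINGS = (
    ("eqtl", "eqtl"),
    ("eqtl", "loop"),
    ("eqtl_interacting", "loop"),
    ("random", "loop"),
    ("random", "eqtl_interacting"),
)


def category_correlation_contrast(
    eqtls: Sequence[EqtlAssociation],
    looped_pairs: Sequence[LoopedEqtlPair],
    calls: EqtlGeneCalls,
    matrix: ExpressionMatrix,
    log_transform: bool = True,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Expression correlation of gene pairs sharing an eQTL locus.

    For every SNP locus, genes in the five category pairings are paired and
    their expression Pearson r computed; self-pairs are excluded. Returns the
    per-pairing r distributions and a matrix of pairwise two-sided Wilcoxon
    rank-sum p-values between pairings.
    """
    by_snp: dict[tuple[str, int], dict[str, set[str]]] = {}

    def bucket(snp, group, gid):
        by_snp.setdefault(snp, {}).setdefault(group, set()).add(gid)

    looped_set = {(p.eqtl.snp_chrom, p.eqtl.snp_pos, p.eqtl.gene_id) for p in looped_pairs}
    for e in eqtls:
        snp = (e.snp_chrom, e.snp_pos)
        if (e.snp_chrom, e.snp_pos, e.gene_id) in looped_set:
            bucket(snp, "loop", e.gene_id)
        else:
            bucket(snp, "eqtl", e.gene_id)
    for e, gid in calls.interacting_links:
        bucket((e.snp_chrom, e.snp_pos), "eqtl_interacting", gid)
    for e, gid in calls.random_links:
        bucket((e.snp_chrom, e.snp_pos), "random", gid)

    have = set(matrix.gene_ids)
    dists: dict[str, np.ndarray] = {}
    for ga, gb in PAIRINGS:
        pairs = set()
        for groups in by_snp.values():
            for x in groups.get(ga, ()):
                for y in groups.get(gb, ()):
                    if x != y and x in have and y in have:
                        pairs.add(tuple(sorted((x, y))))
        key = f"{ga}:{gb}"
        dists[key] = (
            pair_correlations(matrix, sorted(pairs), log_transform)
            if pairs
            else np.empty(0)
        )

    keys = list(dists)
    pmat = pd.DataFrame(np.nan, index=keys, columns=keys)
    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            if dists[ki].size and dists[kj].size:
                p = float(stats.mannwhitneyu(dists[ki], dists[kj], alternative="two-sided").pvalue)
                pmat.loc[ki, kj] = pmat.loc[kj, ki] = p
    return dists, pmat
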