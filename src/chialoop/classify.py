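"""Loop, gene and distal-element classification, plus the PPI network.

PPI: a loop whose two anchors overlap promoter-proximal regions of at least
one pair of *different* genes. PDI: one anchor overlaps a distal element,
the other a promoter-proximal region. When a loop satisfies both
configurations PPI takes precedence (a flag allows dual labels). Genes are
partitioned into anchor genes (promoter overlaps a loop anchor), basal genes
(H3K4me3 or RNAPII peak but no loop) and other genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomeIndex, Loop, Peak
from .elements import DistalElement, PromoterRegion

LOOP_PPI = "PPI"
LOOP_PDI = "PDI"
LOOP_OTHER = "other"


@dataclass(frozen=True)
class LoopClass:
    loop: Loop
    label: str
    gene_ids_A: tuple[str, ...]
    gene_ids_B: tuple[str, ...]
    distal_ids_A: tuple[str, ...]
    distal_ids_B: tuple[str, ...]
    dual: tuple[str, ...] = ()

    @property
    def ppi_gene_pairs(self) -> list[tuple[str, str]]:
        """Cross-anchor pairs of distinct genes, canonically ordered."""
        pairs = {
            tuple(sorted((ga, gb)))
            for ga in self.gene_ids_A
            for gb in self.gene_ids_B
            if ga != gb
        }
        return sorted(pairs)


def classify_loops(
    loops: Sequence[Loop],
    promoters: Sequence[PromoterRegion],
    distal_elements: Sequence[DistalElement],
    dual_labels: bool = False,
) -> list[LoopClass]:
    """Label every loop as PPI, PDI or other (a total partition)."""
    prom_idx = GenomeIndex()
    for p in promoters:
        prom_idx.add(p.region, p.gene_id)
    de_idx = GenomeIndex()
    for d in distal_elements:
        de_idx.add(d.region, d.source_peak_id)

    out: list[LoopClass] = []
    for lo in loops:
        genes_a = tuple(sorted(set(prom_idx.query(lo.anchorA))))
        genes_b = tuple(sorted(set(prom_idx.query(lo.anchorB))))
        des_a = tuple(sorted(set(de_idx.query(lo.anchorA))))
        des_b = tuple(sorted(set(de_idx.query(lo.anchorB))))
        is_ppi = any(ga != gb for ga in genes_a for gb in genes_b)
        is_pdi = (genes_a and des_b) or (genes_b and des_a)
        if is_ppi:
            label = LOOP_PPI
        elif is_pdi:
            label = LOOP_PDI
        else:
            label = LOOP_OTHER
        dual = ()
        if dual_labels and is_ppi and is_pdi:
            dual = (LOOP_PPI, LOOP_PDI)
        out.append(LoopClass(lo, label, genes_a, genes_b, des_a, des_b, dual))
    return out


GENE_ANCHOR = "anchor"
GENE_BASAL = "basal"
GENE_OTHER = "other"


def classify_genes(
    genes: Sequence[GeneModel],
    promoters: Sequence[PromoterRegion],
    loops: Sequence[Loop],
    peaks: Sequence[Peak],
) -> dict[str, str]:
    """Total partition of genes into anchor / basal / other categories."""
    anchor_idx = GenomeIndex()
    for lo in loops:
        anchor_idx.add(lo.anchorA, lo)
        anchor_idx.add(lo.anchorB, lo)
    peak_idx = GenomeIndex.from_intervals([p.region for p in peaks])
    prom_by_gene = {p.gene_id: p.region for p in promoters}

    out: dict[str, str] = {}
    for g in genes:
        prom = prom_by_gene.get(g.gene_id)
        if prom is not None and anchor_idx.any_overlap(prom):
            out[g.gene_id] = GENE_ANCHOR
        elif (prom is not None and peak_idx.any_overlap(prom)) or peak_idx.any_overlap(g.body):
            out[g.gene_id] = GENE_BASAL
        else:
            out[g.gene_id] = GENE_OTHER
    return out


def classify_distal_elements(loop_classes: Sequence[LoopClass]) -> dict[str, str]:
    """Single vs multiple classification of PDI distal elements.

    An element is "multiple" when its PDIs reach >= 2 distinct genes (distinct
    genes, not distinct loops), else "single".
    """
    targets: dict[str, set[str]] = {}
    for lc in loop_classes:
        if lc.label != LOOP_PDI and LOOP_PDI not in lc.dual:
            continue
        for des, genes in ((lc.distal_ids_A, lc.gene_ids_B), (lc.distal_ids_B, lc.gene_ids_A)):
            if des and genes:
                for d in des:
                    targets.setdefault(d, set()).update(genes)
    return {d: ("multiple" if len(gs) >= 2 else "single") for d, gs in targets.items()}


def compare_anchor_peak_intensity(
    peaks: Sequence[Peak], loops: Sequence[Loop]
) -> dict[str, float]:
    """Anchor vs non-anchor peak intensity, Wilcoxon rank-sum (two-sided).

    A peak is an anchor peak when it overlaps any loop anchor by >= 1 bp.
    """
    anchor_idx = GenomeIndex()
    for lo in loops:
        anchor_idx.add(lo.anchorA, lo)
        anchor_idx.add(lo.anchorB, lo)
    anchor_vals, other_vals = [], []
    for p in peaks:
        (anchor_vals if anchor_idx.any_overlap(p.region) else other_vals).append(p.intensity)
    if not anchor_vals or not other_vals:
        raise ValueError("both anchor and non-anchor peak groups must be nonempty")
    a, o = np.asarray(anchor_vals), np.asarray(other_vals)
    res = stats.mannwhitneyu(a, o, alternative="two-sided")
    return {
        "n_anchor": len(a),
        "n_non_anchor": len(o),
        "anchor_median": float(np.median(a)),
        "non_anchor_median": float(np.median(o)),
        "anchor_q1": float(np.percentile(a, 25)),
        "anchor_q3": float(np.percentile(a, 75)),
        "non_anchor_q1": float(np.percentile(o, 25)),
        "non_anchor_q3": float(np.percentile(o, 75)),
        "p_value": float(res.pvalue),
    }


def build_ppi_network(
    loop_classes: Sequence[LoopClass], expression: Mapping[str, float] | None = None
) -> nx.Graph:
    """Undirected gene graph; one edge per PPI gene pair, max PET count kept."""
    g = nx.Graph()
    for lc in loop_classes:
        if lc.label != LOOP_PPI:
            continue
        for ga, gb in lc.ppi_gene_pairs:
            if g.has_edge(ga, gb):
                g[ga][gb]["pet_count"] = max(g[ga][gb]["pet_count"], lc.loop.pet_count)
            else:
                g.add_edge(ga, gb, pet_count=lc.loop.pet_count)
    if expression is not None:
        for node in g.nodes:
            g.nodes[node]["fpkm"] = float(expression.get(node, float("nan")))
    return g


def degree_expression_summary(network: nx.Graph) -> pd.DataFrame:
    """Per-gene degree and expression, for degree-vs-FPKM analysis."""
    rows = [
        (n, network.degree(n), network.nodes[n].get("fpkm", float("nan")))
        for n in sorted(network.nodes)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "degree", "fpkm"])


def degree_assortativity_pairs(network: nx.Graph) -> pd.DataFrame:
    """Degree of each gene vs the degree of its partner, one row per edge end."""
    rows = []
    for u, v in network.edges:
        rows.append((u, network.degree(u), v, network.degree(v)))
        rows.append((v, network.degree(v), u, network.degree(u)))
    return pd.DataFrame(rows, columns=["gene", "degree", "partner", "partner_degree"])


def top_subnetworks(
    network: nx.Graph, n: int = 100, min_pet_count: int = 5
) -> list[set[str]]:
    """Largest connected components of the strong-PPI subgraph.

    Only edges with pet_count >= ``min_pet_count`` (i.e. strictly greater
    than 4 at the default) participate; components are ranked by node count,
    ties broken by lexicographically smallest member for determinism.
    """
    strong = nx.Graph(
        (u, v, d) for u, v, d in network.edges(data=True) if d["pet_count"] >= min_pet_count
    )
    comps = sorted(nx.connected_components(strong), key=lambda c: (-len(c), min(c)))
    return [set(c) for c in comps[:n]]
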