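"""Independent brute-force reference implementations used only by tests.

These deliberately avoid pandas groupbys, interval trees and vectorization:
plain dictionaries and loops, so they share no code path with the package.
"""

from __future__ import annotations

import math


def brute_lumrs(calls, bin_size=200, thresholds=None, min_coverage=3):
    """Per-bin scan LUMR caller. Returns list of (chrom, start, end)."""
    thr = thresholds or {"CG": 0.2, "CHG": 0.1, "CHH": 0.1}
    sums = {}  # (chrom, bin) -> context -> [meth, total]
    for c in calls:
        if c.n_total < min_coverage:
            continue
        key = (c.chrom, c.pos // bin_size)
        ctx = sums.setdefault(key, {})
        m, t = ctx.get(c.context, (0, 0))
        ctx[c.context] = (m + c.n_meth, t + c.n_total)
    passing = []
    for (chrom, b), ctx in sums.items():
        ok = True
        for context, (m, t) in ctx.items():
            if t > 0 and m / t >= thr[context]:
                ok = False
        if ok:
            passing.append((chrom, b))
    passing.sort()
    regions = []
    for chrom, b in passing:
        if regions and regions[-1][0] == chrom and regions[-1][2] == b * bin_size:
            regions[-1] = (chrom, regions[-1][1], (b + 1) * bin_size)
        else:
            regions.append((chrom, b * bin_size, (b + 1) * bin_size))
    return regions


def brute_breadth_cv(values_by_gene, threshold=1.0):
    """values_by_gene: dict gene -> list of FPKM. Returns gene -> (breadth, cv)."""
    out = {}
    for gene, vals in values_by_gene.items():
        breadth = sum(1 for v in vals if v > threshold)
        n = len(vals)
        mean = sum(vals) / n
        if n < 2 or mean == 0:
            cv = float("nan")
        else:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            cv = math.sqrt(var) / mean
        out[gene] = (breadth, cv)
    return out


def brute_degrees(edges):
    """Incidence count per node from an undirected edge list (no parallel edges)."""
    seen = set()
    deg = {}
    for u, v in edges:
        e = tuple(sorted((u, v)))
        if e in seen or u == v:
            continue
        seen.add(e)
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    return deg


def brute_snp_annotation(snps, promoters, elements, gene_bodies):
    """snps: (chrom,pos); regions: (chrom,start,end) lists. Precedence order."""
    def hit(regions, chrom, pos):
        return any(c == chrom and s <= pos < e for c, s, e in regions)

    labels = []
    for chrom, pos in snps:
        if hit(promoters, chrom, pos):
            labels.append("promoter_proximal")
        elif hit(elements, chrom, pos):
            labels.append("distal_element")
        elif hit(gene_bodies, chrom, pos):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    return labels
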