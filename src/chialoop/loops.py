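"""PET categorization, loop calling, loop-set merging and contact matrices.

The loop caller reproduces the standard ChIA-PET filtering: inter-ligation
PETs are clustered into anchors (tag extension followed by interval union),
candidate anchor pairs with fewer than 3 supporting PETs are discarded, and a
surviving pair must have at least one anchor overlapping a ChIP peak of the
matching mark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .core import GenomeIndex, GenomicInterval, Loop, Peak, Pet, merge_intervals

PET_SELF = "self_ligation"
PET_INTER = "inter_ligation"
PET_INTERCHROM = "interchromosomal"


def categorize_pets(pets: Sequence[Pet], self_span_threshold: int = 8000) -> list[Pet]:
    """Partition PETs into self-ligation / inter-ligation / interchromosomal.

    Same-chromosome PETs whose midpoint span is strictly below the threshold
    are self-ligation products (one fragment, both ends sequenced); the rest
    are genuine inter-ligation contacts. The three categories are exhaustive
    and disjoint.
    """
    if self_span_threshold < 0:
        raise ValueError("self_span_threshold must be >= 0")
    out = []
    for p in pets:
        if not p.intrachromosomal:
            cat = PET_INTERCHROM
        elif p.span < self_span_threshold:
            cat = PET_SELF
        else:
            cat = PET_INTER
        out.append(replace(p, category=cat))
    return out


def _build_anchors(
    pets: Sequence[Pet], anchor_extension: int
) -> tuple[list[GenomicInterval], GenomeIndex]:
    tags = []
    for p in pets:
        for t in (p.tagA, p.tagB):
            tags.append(
                GenomicInterval(t.chrom, max(0, t.start - anchor_extension), t.end + anchor_extension)
            )
    anchors = merge_intervals(tags)
    idx = GenomeIndex()
    for i, a in enumerate(anchors):
        idx.add(a, i)
    return anchors, idx


def call_loops(
    inter_pets: Sequence[Pet],
    peaks: Sequence[Peak],
    min_pet_count: int = 3,
    anchor_extension: int = 500,
    source: str = "",
) -> list[Loop]:
    """Call loops from inter-ligation PETs with PET-count and peak filters.

    Tags extended by ``anchor_extension`` on each side are unioned into
    anchor regions; PETs are grouped by their (anchorA, anchorB) pair. A pair
    is emitted when its summed PET count is >= ``min_pet_count`` and at least
    one anchor overlaps >= 1 peak; ``peak_support`` records both/one.
    Output is sorted canonically and independent of input PET order.
    """
    if min_pet_count < 1:
        raise ValueError("min_pet_count must be >= 1")
    if not inter_pets:
        return []
    anchors, anchor_idx = _build_anchors(inter_pets, anchor_extension)

    counts: dict[tuple[int, int], int] = {}
    for p in inter_pets:
        ia = anchor_idx.query_point(p.tagA.chrom, min(p.tagA.midpoint, p.tagA.end - 1))
        ib = anchor_idx.query_point(p.tagB.chrom, min(p.tagB.midpoint, p.tagB.end - 1))
        if not ia or not ib:  # pragma: no cover - anchors cover all tags
            continue
        key = tuple(sorted((ia[0], ib[0])))
        if key[0] == key[1]:
            continue  # both tags merged into one anchor: not a loop
        counts[key] = counts.get(key, 0) + p.count

    peak_idx = GenomeIndex.from_intervals([pk.region for pk in peaks])
    out: list[Loop] = []
    for (i, j), n in counts.items():
        if n < min_pet_count:
            continue
        a, b = anchors[i], anchors[j]
        hit_a = peak_idx.any_overlap(a)
        hit_b = peak_idx.any_overlap(b)
        if not (hit_a or hit_b):
            continue
        support = "both" if (hit_a and hit_b) else "one"
        out.append(Loop(a, b, pet_count=n, source=source, peak_support=support))
    out.sort(key=lambda lo: (lo.anchorA.chrom, lo.anchorA.start, lo.anchorB.chrom, lo.anchorB.start))
    return out


def classify_loop_locality(loops: Sequence[Loop]) -> dict[str, int]:
    """Counts of intra- vs inter-chromosomal loops (a disjoint partition)."""
    intra = sum(1 for lo in loops if lo.intrachromosomal)
    return {"intra": intra, "inter": len(loops) - intra, "total": len(loops)}


def merge_loop_sets(set_a: Sequence[Loop], set_b: Sequence[Loop]) -> list[Loop]:
    """Unify loops found in both sets (e.g. H3K4me3- and RNAPII-derived).

    Two loops are the same contact when both anchors reciprocally overlap by
    >= 1 bp. Matched pairs are emitted once with summed PET counts and
    source="merged" (anchors unioned); unmatched loops pass through.
    """
    matched_b: set[int] = set()
    out: list[Loop] = []
    for la in set_a:
        merged = None
        for j, lb in enumerate(set_b):
            if j in matched_b:
                continue
            if la.anchorA.overlaps(lb.anchorA) and la.anchorB.overlaps(lb.anchorB):
                merged = (j, lb)
                break
        if merged is None:
            out.append(la)
        else:
            j, lb = merged
            matched_b.add(j)
            a = GenomicInterval(
                la.anchorA.chrom,
                min(la.anchorA.start, lb.anchorA.start),
                max(la.anchorA.end, lb.anchorA.end),
            )
            b = GenomicInterval(
                la.anchorB.chrom,
                min(la.anchorB.start, lb.anchorB.start),
                max(la.anchorB.end, lb.anchorB.end),
            )
            out.append(
                Loop(a, b, pet_count=la.pet_count + lb.pet_count, source="merged",
                     peak_support=la.peak_support or lb.peak_support)
            )
    out.extend(lb for j, lb in enumerate(set_b) if j not in matched_b)
    return out


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact-count matrix at a fixed resolution."""

    chrom: str
    resolution: int
    observed: np.ndarray
    normalized: np.ndarray | None = None


def contact_matrix(
    pets: Sequence[Pet], resolution: int, chrom: str, chrom_length: int
) -> ContactMatrix:
    """Bin intrachromosomal PET tag pairs into a symmetric count matrix."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n = int(np.ceil(chrom_length / resolution))
    obs = np.zeros((n, n), dtype=float)
    for p in pets:
        if p.tagA.chrom != chrom or p.tagB.chrom != chrom:
            continue
        i = p.tagA.midpoint // resolution
        j = p.tagB.midpoint // resolution
        obs[i, j] += p.count
        if i != j:
            obs[j, i] += p.count
    return ContactMatrix(chrom, resolution, obs)


def distance_normalize(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected normalization; expected = mean count at each distance.

    Diagonals with zero total mass are left at 0 rather than producing NaN.
    """
    obs = matrix.observed
    n = obs.shape[0]
    norm = np.zeros_like(obs)
    for d in range(n):
        diag = np.diagonal(obs, offset=d)
        mean = diag.mean() if diag.size else 0.0
        if mean > 0:
            idx = np.arange(n - d)
            norm[idx, idx + d] = diag / mean
            if d > 0:
                norm[idx + d, idx] = diag / mean
    return ContactMatrix(matrix.chrom, matrix.resolution, obs, norm)


def loop_span_summary(loops: Sequence[Loop]) -> dict[str, float]:
    spans = [lo.span for lo in loops if lo.intrachromosomal]
    if not spans:
        return {"n": 0, "median_span": float("nan"), "mean_span": float("nan")}
    arr = np.asarray(spans, dtype=float)
    return {"n": len(arr), "median_span": float(np.median(arr)), "mean_span": float(arr.mean())}
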