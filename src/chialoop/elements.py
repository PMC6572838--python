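"""Annotation of promoter-proximal regions, LUMRs and candidate distal elements.

Promoter-proximal regions are strand-oriented windows around the TSS
(2 kb upstream, 1.5 kb downstream by default). LUMRs (low and unmethylated
methylation regions) are runs of 200-bp bins whose weighted mean methylation
is below strict per-context thresholds (CG < 0.2, CHG < 0.1, CHH < 0.1).
Candidate distal elements are MNase-hypersensitive peaks from the heavy
digest that survive four filters: no overlap with a light-digest peak, with
any gene body, with any gene body +/- 2 kb, or with an H3K4me3 peak — and
that overlap at least one LUMR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import (
    METH_CONTEXTS,
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    MethylationCall,
    Peak,
    merge_intervals,
)
from .io import methylation_frame

DEFAULT_LUMR_THRESHOLDS = {"CG": 0.2, "CHG": 0.1, "CHH": 0.1}


@dataclass(frozen=True)
class PromoterRegion:
    region: GenomicInterval
    gene_id: str


@dataclass(frozen=True)
class Lumr:
    region: GenomicInterval
    mean_levels: tuple[float, float, float]  # (CG, CHG, CHH); NaN = no coverage


@dataclass(frozen=True)
class DistalElement:
    region: GenomicInterval
    source_peak_id: str
    lumr_ids: tuple[int, ...]


def call_promoter_regions(
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 1500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PromoterRegion]:
    """Strand-aware TSS windows, clipped to chromosome bounds.

    For a + gene the window is [tss - upstream, tss + downstream); for a -
    gene it is mirrored to [tss - downstream, tss + upstream), so that
    "upstream" always points away from the gene body.
    """
    out: list[PromoterRegion] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        elif g.strand == "-":
            start, end = g.tss - downstream, g.tss + upstream
        else:  # pragma: no cover - GeneModel forbids this
            raise ValueError(f"gene {g.gene_id} has no strand")
        start = max(0, start)
        if chrom_lengths is not None and g.chrom in chrom_lengths:
            end = min(end, chrom_lengths[g.chrom])
        out.append(PromoterRegion(GenomicInterval(g.chrom, start, end), g.gene_id))
    return out


def call_lumrs(
    calls: Sequence[MethylationCall],
    bin_size: int = 200,
    thresholds: Mapping[str, float] | None = None,
    min_coverage: int = 3,
) -> list[Lumr]:
    """Call LUMRs by binning methylation and thresholding per context.

    The genome is tiled in non-overlapping ``bin_size`` bins. Within each bin
    the per-context level is the coverage-weighted mean sum(n_meth)/sum(n_total)
    over sites with n_total >= min_coverage. A bin passes when every covered
    context is strictly below its threshold; a context with no covered site
    imposes no constraint. Bins with no covered site in any context are not
    callable and never emitted. Adjacent passing bins are merged into one
    region, reported with the weighted mean levels of the merged region.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    thr = dict(DEFAULT_LUMR_THRESHOLDS if thresholds is None else thresholds)
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        if not calls:
            return []
        df = methylation_frame(calls)
    if df.empty:
        return []
    df = df[df["n_total"] >= min_coverage]
    if df.empty:
        return []
    df = df.assign(bin=df["pos"] // bin_size)
    agg = (
        df.groupby(["chrom", "bin", "context"], sort=True)[["n_meth", "n_total"]]
        .sum()
        .reset_index()
    )
    agg["level"] = agg["n_meth"] / agg["n_total"]
    # a bin passes iff every covered context is strictly below threshold
    agg["fail"] = agg["level"] >= agg["context"].map(thr).astype(float)
    per_bin = agg.groupby(["chrom", "bin"])["fail"].any()
    passing = per_bin[~per_bin].index

    out: list[Lumr] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, b in passing:
        by_chrom.setdefault(chrom, []).append(int(b))

    # per-(chrom,bin,context) sums for merged-region levels
    sums = agg.set_index(["chrom", "bin", "context"])[["n_meth", "n_total"]]

    for chrom in sorted(by_chrom):
        bins = sorted(by_chrom[chrom])
        runs: list[list[int]] = [[bins[0]]]
        for b in bins[1:]:
            if b == runs[-1][-1] + 1:
                runs[-1].append(b)
            else:
                runs.append([b])
        for run in runs:
            meth = {c: 0 for c in METH_CONTEXTS}
            tot = {c: 0 for c in METH_CONTEXTS}
            for b in run:
                for c in METH_CONTEXTS:
                    key = (chrom, b, c)
                    if key in sums.index:
                        meth[c] += int(sums.loc[key, "n_meth"])
                        tot[c] += int(sums.loc[key, "n_total"])
            levels = tuple(
                meth[c] / tot[c] if tot[c] > 0 else float("nan") for c in METH_CONTEXTS
            )
            region = GenomicInterval(chrom, run[0] * bin_size, (run[-1] + 1) * bin_size)
            out.append(Lumr(region, levels))
    return out


def call_distal_elements(
    heavy_peaks: Sequence[Peak],
    light_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    h3k4me3_peaks: Sequence[Peak],
    lumrs: Sequence[Lumr],
    gene_flank: int = 2000,
    min_overlap: int = 1,
) -> list[DistalElement]:
    """Filter heavy-digest MNase peaks down to LUMR-supported distal elements.

    The four rules are pure set filters and commute; they are applied in a
    fixed order only for speed.
    """
    light_idx = GenomeIndex.from_intervals([p.region for p in light_peaks])
    k4_idx = GenomeIndex.from_intervals([p.region for p in h3k4me3_peaks])
    flank_idx = GenomeIndex()
    for g in genes:
        b = g.body
        flank_idx.add(GenomicInterval(b.chrom, max(0, b.start - gene_flank), b.end + gene_flank), g)
    lumr_idx = GenomeIndex()
    for i, lm in enumerate(lumrs):
        lumr_idx.add(lm.region, i)

    out: list[DistalElement] = []
    for i, p in enumerate(heavy_peaks):
        r = p.region
        if light_idx.any_overlap(r, min_overlap):
            continue
        # gene body +/- flank covers the plain gene-body exclusion too
        if flank_idx.any_overlap(r, min_overlap):
            continue
        if k4_idx.any_overlap(r, min_overlap):
            continue
        hit_lumrs = tuple(sorted(lumr_idx.query(r)))
        hit_lumrs = tuple(
            j for j in hit_lumrs
            if min(lumrs[j].region.end, r.end) - max(lumrs[j].region.start, r.start) >= min_overlap
        )
        if not hit_lumrs:
            continue
        out.append(DistalElement(r, p.name or f"heavy_{i}", hit_lumrs))
    return out


def coverage_from_peaks(
    peaks: Sequence[Peak], chrom_lengths: Mapping[str, int], bin: int = 50
) -> dict[str, np.ndarray]:
    """Rasterize peak intensity onto fixed-width genome bins (RPKM-like track)."""
    track = {
        chrom: np.zeros(int(np.ceil(length / bin)), dtype=float)
        for chrom, length in chrom_lengths.items()
    }
    for p in peaks:
        arr = track.get(p.region.chrom)
        if arr is None:
            continue
        b0 = p.region.start // bin
        b1 = (p.region.end - 1) // bin + 1
        arr[b0 : min(b1, len(arr))] += p.intensity
    return track


def signal_profile(
    regions: Sequence[tuple[str, str, int, str]],
    coverage: Mapping[str, np.ndarray],
    flank: int = 3000,
    bin: int = 50,
) -> pd.DataFrame:
    """Per-region signal profile centered on a point, in fixed bins.

    ``regions`` are (region_id, chrom, center, strand) tuples; for TSS
    profiles the center is the TSS. Minus-strand rows are flipped so that
    upstream is always on the left. Bins outside the chromosome are NaN
    (missing), not zero. Columns are bp offsets of bin left edges relative
    to the center.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    n_side = flank // bin
    offsets = np.arange(-n_side, n_side) * bin
    rows = {}
    for region_id, chrom, center, strand in regions:
        arr = coverage[chrom]
        center_bin = center // bin
        idx = center_bin + np.arange(-n_side, n_side)
        vals = np.full(idx.shape, np.nan)
        ok = (idx >= 0) & (idx < len(arr))
        vals[ok] = arr[idx[ok]]
        if strand == "-":
            vals = vals[::-1]
        rows[region_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=offsets)


def cluster_tss_states(
    profiles_by_mark: Mapping[str, pd.DataFrame], k: int = 15, seed: int = 0
) -> pd.Series:
    """K-means over concatenated per-mark TSS profiles.

    Rows (genes) must agree across marks. NaN bins are replaced by the
    per-column mean before clustering. Cluster ids are relabeled by
    descending cluster size so label 0 is always the largest state.
    """
    marks = sorted(profiles_by_mark)
    mats = [profiles_by_mark[m] for m in marks]
    index = mats[0].index
    for m in mats[1:]:
        if not m.index.equals(index):
            raise ValueError("profile matrices must share the same gene index")
    X = np.hstack([m.to_numpy(dtype=float) for m in mats])
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)
    X = np.where(np.isnan(X), col_mean, X)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    order = pd.Series(raw).value_counts(sort=True).index  # descending size
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[v] for v in raw], index=index, name="tss_state")
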