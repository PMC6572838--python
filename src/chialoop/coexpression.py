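"""Expression breadth/CV analysis and looped-pair co-expression testing.

The co-expression test compares the Pearson correlation (across tissues) of
gene pairs joined by promoter-promoter loops against two random controls:

- mode A: random gene pairs from the same chromosome;
- mode B: random gene pairs matched to the observed pairs on genomic
  distance (20 equal-width bins on log distance) and restricted to genes
  carrying an H3K4me3 or RNAPII peak.

Mode B mirrors the observed per-bin pair counts exactly, replicate by
replicate; candidate pairs identical to any observed pair are rejected and
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel
from .io import ExpressionMatrix

Pair = tuple[str, str]


def expression_breadth_and_cv(
    matrix: ExpressionMatrix,
    expressed_threshold: float = 1.0,
    sample_sd: bool = True,
) -> pd.DataFrame:
    """Per-gene expression breadth and coefficient of variation.

    Breadth counts tissues with FPKM strictly above ``expressed_threshold``.
    CV = SD / mean with the sample (n-1) SD by default; genes with zero mean
    or a single tissue get cv = NaN (flagged undefined).
    """
    vals = matrix.values.to_numpy(dtype=float)
    breadth = (vals > expressed_threshold).sum(axis=1)
    mean = vals.mean(axis=1)
    ddof = 1 if sample_sd else 0
    if vals.shape[1] <= ddof:
        sd = np.full(vals.shape[0], np.nan)
    else:
        sd = vals.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"gene_id": matrix.gene_ids, "breadth": breadth, "mean": mean, "sd": sd, "cv": cv}
    ).set_index("gene_id")


def rank_housekeeping_tissue_specific(
    records: pd.DataFrame, n: int = 500
) -> tuple[list[str], list[str]]:
    """Lowest-CV genes (stably expressed: housekeeping) vs highest-CV genes.

    Genes with undefined CV are excluded; ties are broken by gene id so the
    two sets are deterministic.
    """
    defined = records.dropna(subset=["cv"])
    if len(defined) < 2 * n:
        raise ValueError(f"need >= {2 * n} genes with defined CV, have {len(defined)}")
    # stable sort by CV with gene-id (index) tie-break
    ordered = defined.sort_index(kind="mergesort").sort_values("cv", kind="mergesort")
    ids = list(ordered.index)
    return ids[:n], ids[-n:]


# ---------------------------------------------------------------------------
# Distance-matched random pairs
# ---------------------------------------------------------------------------


def pair_distances(pairs: Sequence[Pair], tss: Mapping[str, tuple[str, int]]) -> np.ndarray:
    """TSS-to-TSS distance for each intra-chromosomal gene pair."""
    out = np.empty(len(pairs), dtype=float)
    for i, (a, b) in enumerate(pairs):
        ca, pa = tss[a]
        cb, pb = tss[b]
        if ca != cb:
            raise ValueError(f"pair ({a}, {b}) is not intra-chromosomal")
        out[i] = abs(pa - pb)
    return out


def log_distance_bins(distances: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Equal-width bin edges on the natural-log distance scale."""
    if (distances <= 0).any():
        raise ValueError("pair distances must be positive")
    lo, hi = np.log(distances.min()), np.log(distances.max())
    if lo == hi:
        hi = lo + 1e-9
    return np.linspace(lo, hi, n_bins + 1)


def assign_bins(distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(np.log(distances), edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def tss_map(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int]]:
    return {g.gene_id: (g.chrom, g.tss) for g in genes}


def matched_random_pairs(
    observed_pairs: Sequence[Pair],
    genes: Sequence[GeneModel],
    mode: str,
    peak_gene_ids: set[str] | None = None,
    n_bins: int = 20,
    reps: int = 1000,
    seed: int = 0,
    max_attempts: int = 2000,
) -> list[list[Pair]]:
    """Draw ``reps`` replicate null pair sets, one random pair per observed pair.

    mode "A": uniform random same-chromosome pairs from the gene universe.
    mode "B": each random pair's log TSS distance falls in the same of the
    ``n_bins`` bins as its observed counterpart, and both genes must carry a
    peak (``peak_gene_ids``). Pairs equal to any observed pair are rejected
    and resampled; a bin where no eligible pair can be found within
    ``max_attempts`` raises an error naming the bin.
    """
    if mode not in ("A", "B"):
        raise ValueError("mode must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    tss = tss_map(genes)
    observed_set = {tuple(sorted(p)) for p in observed_pairs}

    if mode == "A":
        by_chrom: dict[str, list[str]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.gene_id)
        chroms = [c for c, ids in sorted(by_chrom.items()) if len(ids) >= 2]
        if not chroms:
            raise ValueError("no chromosome holds two genes")
        out = []
        for _ in range(reps):
            rep: list[Pair] = []
            for _pair in observed_pairs:
                for _try in range(max_attempts):
                    chrom = chroms[rng.integers(len(chroms))]
                    ids = by_chrom[chrom]
                    i, j = rng.choice(len(ids), size=2, replace=False)
                    cand = tuple(sorted((ids[i], ids[j])))
                    if cand not in observed_set:
                        rep.append(cand)
                        break
                else:
                    raise RuntimeError("could not draw a same-chromosome random pair")
            out.append(rep)
        return out

    # mode B
    if peak_gene_ids is None:
        raise ValueError("mode B requires peak_gene_ids")
    eligible: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss)):
        if g.gene_id in peak_gene_ids:
            names.setdefault(g.chrom, []).append(g.gene_id)
            eligible.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    eligible = {c: np.asarray(v, dtype=float) for c, v in eligible.items()}
    chrom_list = sorted(eligible)
    if not chrom_list:
        raise ValueError("no peak-bearing genes available for mode B")

    distances = pair_distances(list(observed_pairs), tss)
    edges = log_distance_bins(distances, n_bins)
    bins = assign_bins(distances, edges)

    out = []
    for _ in range(reps):
        rep = []
        for b in bins:
            d_lo, d_hi = np.exp(edges[b]), np.exp(edges[b + 1])
            pair = _draw_pair_in_distance_range(
                rng, chrom_list, eligible, names, d_lo, d_hi, observed_set, max_attempts
            )
            if pair is None:
                raise RuntimeError(
                    f"no eligible random pair in distance bin {b} "
                    f"[{d_lo:.0f}, {d_hi:.0f}] after {max_attempts} attempts"
                )
            rep.append(pair)
        out.append(rep)
    return out


def _draw_pair_in_distance_range(
    rng, chrom_list, eligible, names, d_lo, d_hi, observed_set, max_attempts
):
    for _ in range(max_attempts):
        chrom = chrom_list[rng.integers(len(chrom_list))]
        pos = eligible[chrom]
        if len(pos) < 2:
            continue
        i = int(rng.integers(len(pos)))
        t = pos[i]
        # candidate partners with |tss - t| in [d_lo, d_hi]
        lo_r = np.searchsorted(pos, t + d_lo, side="left")
        hi_r = np.searchsorted(pos, t + d_hi, side="right")
        lo_l = np.searchsorted(pos, t - d_hi, side="left")
        hi_l = np.searchsorted(pos, t - d_lo, side="right")
        cand = list(range(lo_r, hi_r)) + list(range(lo_l, hi_l))
        cand = [j for j in cand if j != i]
        if not cand:
            continue
        j = cand[int(rng.integers(len(cand)))]
        pair = tuple(sorted((names[chrom][i], names[chrom][j])))
        if pair in observed_set:
            continue
        return pair
    return None


# ---------------------------------------------------------------------------
# Correlation test
# ---------------------------------------------------------------------------


def pair_correlations(
    matrix: ExpressionMatrix, pairs: Sequence[Pair], log_transform: bool = True
) -> np.ndarray:
    """Pearson r across tissues for each gene pair (on log2(FPKM+1) by default)."""
    vals = matrix.values
    X = np.log2(vals.to_numpy(dtype=float) + 1.0) if log_transform else vals.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(vals.index)}
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.divide(X - mean, sd, out=np.zeros_like(X), where=sd > 0)
    n = X.shape[1]
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        out[k] = float(Z[index[a]] @ Z[index[b]]) / n
    return out


@dataclass
class PairCorrelationResult:
    observed_r: np.ndarray
    null_r: dict[str, np.ndarray]  # pooled across replicates, per mode
    null_rep_means: dict[str, np.ndarray]  # one mean per replicate, per mode
    mean_observed: float = 0.0
    mean_diff: dict[str, float] = field(default_factory=dict)
    t_p: dict[str, float] = field(default_factory=dict)
    empirical_p: dict[str, float] = field(default_factory=dict)


def coexpression_test(
    observed_pairs: Sequence[Pair],
    null_sets: Mapping[str, Sequence[Sequence[Pair]]],
    matrix: ExpressionMatrix,
    log_transform: bool = True,
) -> PairCorrelationResult:
    """Observed vs null pair correlations with T-test and empirical p.

    The primary p-value per null mode is a two-sided two-sample T-test of
    observed r against the pooled null r. The empirical p uses the
    per-replicate null means with the add-one estimator
    (1 + #{null mean >= observed mean}) / (reps + 1).
    """
    obs = pair_correlations(matrix, observed_pairs, log_transform)
    res = PairCorrelationResult(obs, {}, {}, mean_observed=float(obs.mean()))
    for mode, reps in null_sets.items():
        rep_r = [pair_correlations(matrix, rep, log_transform) for rep in reps]
        pooled = np.concatenate(rep_r) if rep_r else np.empty(0)
        means = np.array([r.mean() for r in rep_r])
        res.null_r[mode] = pooled
        res.null_rep_means[mode] = means
        res.mean_diff[mode] = float(obs.mean() - pooled.mean()) if pooled.size else float("nan")
        if pooled.size:
            res.t_p[mode] = float(stats.ttest_ind(obs, pooled, equal_var=False).pvalue)
            res.empirical_p[mode] = float((1 + (means >= obs.mean()).sum()) / (len(means) + 1))
        else:
            res.t_p[mode] = float("nan")
            res.empirical_p[mode] = float("nan")
    return res
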