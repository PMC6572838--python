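"""End-to-end pipeline driver: elements -> loops -> classify -> coexpress -> qtl.

Each stage reads serialized inputs (either the raw bundle or a previous
stage's output files), writes plain-text outputs into the run directory, and
drops a provenance block (parameters, input file digests, stage seed) next to
them. Re-running with the same config and inputs reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import coexpression as coex
from . import elements as elem
from . import io as cio
from . import loops as lp
from . import qtl as qt

log = logging.getLogger("chialoop")

STAGES = ("elements", "loops", "classify", "coexpress", "qtl")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    # input files
    genes: str = ""
    h3k4me3: str = ""
    rnapii: str = ""
    mnase_heavy: str = ""
    mnase_light: str = ""
    methylation: str = ""
    pets: str = ""
    expression: str = ""
    eqtls: str = ""
    gwas: str = ""
    chrom_sizes: str = ""
    outdir: str = "chialoop_run"

    # parameters (field defaults are the analysis defaults)
    promoter_upstream: int = 2000
    promoter_downstream: int = 1500
    lumr_bin_size: int = 200
    lumr_thresholds: dict = field(default_factory=lambda: {"CG": 0.2, "CHG": 0.1, "CHH": 0.1})
    lumr_min_coverage: int = 3
    gene_flank: int = 2000
    self_span_threshold: int = 8000
    min_pet_count: int = 3
    anchor_extension: int = 500
    subnetwork_min_pet_count: int = 5  # strictly greater than 4
    n_subnetworks: int = 100
    expressed_threshold: float = 1.0
    cv_top_n: int = 500
    coexpression_bins: int = 20
    coexpression_reps: int = 1000
    snp_window: int = 4000
    gwas_window: int = 200000
    qtl_sim_reps: int = 1000
    tss_profile_flank: int = 3000
    tss_profile_bin: int = 50
    tss_states_k: int = 15
    contact_resolutions: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.min_pet_count < 1:
            raise PipelineConfigError("min_pet_count must be >= 1")
        if self.lumr_bin_size <= 0:
            raise PipelineConfigError("lumr_bin_size must be > 0")
        if self.self_span_threshold < 0:
            raise PipelineConfigError("self_span_threshold must be >= 0")
        if not all(0 < v <= 1 for v in self.lumr_thresholds.values()):
            raise PipelineConfigError("LUMR thresholds must be in (0, 1]")
        if self.coexpression_bins < 1 or self.coexpression_reps < 1:
            raise PipelineConfigError("coexpression bins/reps must be >= 1")
        if self.snp_window <= 0 or self.gwas_window <= 0:
            raise PipelineConfigError("SNP/GWAS windows must be > 0")
        if self.qtl_sim_reps < 1:
            raise PipelineConfigError("qtl_sim_reps must be >= 1")
        if self.tss_profile_flank % self.tss_profile_bin != 0:
            raise PipelineConfigError("tss_profile_flank must be a multiple of tss_profile_bin")
        if self.cv_top_n < 1:
            raise PipelineConfigError("cv_top_n must be >= 1")
        if any(r <= 0 for r in self.contact_resolutions):
            raise PipelineConfigError("contact resolutions must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    """One independent substream per stage, derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _provenance(outdir: Path, stage: str, params: dict, inputs: list, seed: int) -> None:
    block = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): _digest(p) for p in inputs if p and Path(p).exists()},
        "seed": seed,
    }
    with open(outdir / f"provenance_{stage}.json", "w") as fh:
        json.dump(block, fh, indent=1, sort_keys=True)


def _read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, ln = line.split("\t")[:2]
                out[chrom] = int(ln)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_elements(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    genes = cio.read_gff3(cfg.genes)
    chrom_lengths = _read_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
    promoters = elem.call_promoter_regions(
        genes, cfg.promoter_upstream, cfg.promoter_downstream, chrom_lengths
    )
    cio.write_intervals_bed(
        [p.region for p in promoters], outdir / "promoters.bed",
        names=[p.gene_id for p in promoters],
    )

    meth = pd.read_csv(cfg.methylation, sep="\t")
    lumrs = elem.call_lumrs(meth, cfg.lumr_bin_size, cfg.lumr_thresholds, cfg.lumr_min_coverage)
    cio.write_intervals_bed(
        [l.region for l in lumrs], outdir / "lumrs.bed",
        names=[f"lumr_{i}" for i in range(len(lumrs))],
    )

    heavy = cio.read_bed(cfg.mnase_heavy, "MNase_heavy")
    light = cio.read_bed(cfg.mnase_light, "MNase_light")
    k4 = cio.read_bed(cfg.h3k4me3, "H3K4me3")
    des = elem.call_distal_elements(heavy, light, genes, k4, lumrs, cfg.gene_flank)
    cio.write_intervals_bed(
        [d.region for d in des], outdir / "distal_elements.bed",
        names=[d.source_peak_id for d in des],
    )

    # TSS chromatin-state clustering over H3K4me3 + RNAPII coverage
    if chrom_lengths:
        pol2 = cio.read_bed(cfg.rnapii, "RNAPII")
        regions = [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]
        profiles = {
            mark: elem.signal_profile(
                regions,
                elem.coverage_from_peaks(peaks, chrom_lengths, cfg.tss_profile_bin),
                cfg.tss_profile_flank,
                cfg.tss_profile_bin,
            )
            for mark, peaks in (("H3K4me3", k4), ("RNAPII", pol2))
        }
        k = min(cfg.tss_states_k, len(genes))
        states = elem.cluster_tss_states(profiles, k=k, seed=seed)
        states.to_csv(outdir / "tss_states.tsv", sep="\t", header=True)

    _provenance(
        outdir, "elements",
        {"promoter_upstream": cfg.promoter_upstream,
         "promoter_downstream": cfg.promoter_downstream,
         "lumr_bin_size": cfg.lumr_bin_size, "lumr_thresholds": cfg.lumr_thresholds,
         "lumr_min_coverage": cfg.lumr_min_coverage, "gene_flank": cfg.gene_flank,
         "tss_states_k": cfg.tss_states_k},
        [cfg.genes, cfg.methylation, cfg.mnase_heavy, cfg.mnase_light, cfg.h3k4me3],
        seed,
    )


def stage_loops(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    pets = cio.read_bedpe_pets(cfg.pets)
    pets = lp.categorize_pets(pets, cfg.self_span_threshold)
    counts = {
        c: sum(1 for p in pets if p.category == c)
        for c in (lp.PET_SELF, lp.PET_INTER, lp.PET_INTERCHROM)
    }
    inter = [p for p in pets if p.category == lp.PET_INTER]
    peaks = cio.read_bed(cfg.h3k4me3, "H3K4me3") + cio.read_bed(cfg.rnapii, "RNAPII")
    loops = lp.call_loops(inter, peaks, cfg.min_pet_count, cfg.anchor_extension, source="merged")
    cio.write_bedpe_loops(loops, outdir / "loops.bedpe")
    summary = {
        "pet_categories": counts,
        "loop_locality": lp.classify_loop_locality(loops),
        "span": lp.loop_span_summary(loops),
    }
    with open(outdir / "loops_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    if cfg.contact_resolutions and cfg.chrom_sizes:
        from scipy import io as spio
        from scipy import sparse

        chrom_lengths = _read_chrom_sizes(cfg.chrom_sizes)
        for res in cfg.contact_resolutions:
            for chrom, ln in chrom_lengths.items():
                cm = lp.distance_normalize(lp.contact_matrix(inter, res, chrom, ln))
                spio.mmwrite(
                    str(outdir / f"contacts_{chrom}_{res}.mtx"),
                    sparse.coo_matrix(cm.observed),
                )

    _provenance(
        outdir, "loops",
        {"self_span_threshold": cfg.self_span_threshold,
         "min_pet_count": cfg.min_pet_count, "anchor_extension": cfg.anchor_extension,
         "contact_resolutions": cfg.contact_resolutions},
        [cfg.pets, cfg.h3k4me3, cfg.rnapii],
        seed,
    )


def _load_promoters(outdir: Path) -> list[elem.PromoterRegion]:
    peaks = cio.read_bed(outdir / "promoters.bed")
    return [elem.PromoterRegion(p.region, p.name) for p in peaks]


def _load_distal_elements(outdir: Path) -> list[elem.DistalElement]:
    peaks = cio.read_bed(outdir / "distal_elements.bed")
    return [elem.DistalElement(p.region, p.name, ()) for p in peaks]


def stage_classify(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    loops = cio.read_bedpe_loops(outdir / "loops.bedpe")
    promoters = _load_promoters(outdir)
    des = _load_distal_elements(outdir)
    genes = cio.read_gff3(cfg.genes)
    peaks = cio.read_bed(cfg.h3k4me3, "H3K4me3") + cio.read_bed(cfg.rnapii, "RNAPII")

    loop_classes = cls.classify_loops(loops, promoters, des)
    rows = [
        (lc.loop.anchorA.chrom, lc.loop.anchorA.start, lc.loop.anchorA.end,
         lc.loop.anchorB.chrom, lc.loop.anchorB.start, lc.loop.anchorB.end,
         lc.loop.pet_count, lc.label,
         ",".join(lc.gene_ids_A) or ".", ",".join(lc.gene_ids_B) or ".",
         ",".join(lc.distal_ids_A) or ".", ",".join(lc.distal_ids_B) or ".")
        for lc in loop_classes
    ]
    pd.DataFrame(rows, columns=[
        "chromA", "startA", "endA", "chromB", "startB", "endB",
        "pet_count", "label", "genesA", "genesB", "distalA", "distalB",
    ]).to_csv(outdir / "loop_classes.tsv", sep="\t", index=False)

    gene_cats = cls.classify_genes(genes, promoters, loops, peaks)
    pd.Series(gene_cats, name="category").rename_axis("gene_id").to_csv(
        outdir / "gene_categories.tsv", sep="\t"
    )
    de_cats = cls.classify_distal_elements(loop_classes)
    pd.Series(de_cats, name="class").rename_axis("element_id").sort_index().to_csv(
        outdir / "element_classes.tsv", sep="\t"
    )

    expr = cio.read_expression_matrix(cfg.expression)
    fpkm = dict(zip(expr.gene_ids, expr.values.mean(axis=1)))
    network = cls.build_ppi_network(loop_classes, fpkm)
    cls.degree_expression_summary(network).to_csv(
        outdir / "ppi_network_nodes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(u, v, d["pet_count"]) for u, v, d in network.edges(data=True)],
        columns=["gene_a", "gene_b", "pet_count"],
    ).to_csv(outdir / "ppi_network_edges.tsv", sep="\t", index=False)
    subnets = cls.top_subnetworks(network, cfg.n_subnetworks, cfg.subnetwork_min_pet_count)
    with open(outdir / "top_subnetworks.json", "w") as fh:
        json.dump([sorted(s) for s in subnets], fh, indent=1)

    try:
        intensity = cls.compare_anchor_peak_intensity(peaks, loops)
    except ValueError:
        intensity = None
    with open(outdir / "anchor_peak_intensity.json", "w") as fh:
        json.dump(intensity, fh, indent=1, sort_keys=True)

    _provenance(
        outdir, "classify",
        {"subnetwork_min_pet_count": cfg.subnetwork_min_pet_count,
         "n_subnetworks": cfg.n_subnetworks},
        [cfg.genes, cfg.h3k4me3, cfg.rnapii, cfg.expression,
         outdir / "loops.bedpe", outdir / "promoters.bed", outdir / "distal_elements.bed"],
        seed,
    )


def _ppi_pairs_from_tsv(outdir: Path) -> list[tuple[str, str]]:
    df = pd.read_csv(outdir / "loop_classes.tsv", sep="\t")
    pairs = set()
    for _, row in df[df["label"] == cls.LOOP_PPI].iterrows():
        ga = [] if row["genesA"] == "." else str(row["genesA"]).split(",")
        gb = [] if row["genesB"] == "." else str(row["genesB"]).split(",")
        for a in ga:
            for b in gb:
                if a != b:
                    pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


def stage_coexpress(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    expr = cio.read_expression_matrix(cfg.expression)
    genes = cio.read_gff3(cfg.genes)
    records = coex.expression_breadth_and_cv(expr, cfg.expressed_threshold)
    records.to_csv(outdir / "breadth_cv.tsv", sep="\t")

    n = min(cfg.cv_top_n, len(records.dropna(subset=["cv"])) // 2)
    if n < cfg.cv_top_n:
        log.warning("cv_top_n clamped from %d to %d (gene count)", cfg.cv_top_n, n)
    hk, ts = coex.rank_housekeeping_tissue_specific(records, n) if n else ([], [])
    with open(outdir / "housekeeping_tissue_specific.json", "w") as fh:
        json.dump({"housekeeping": hk, "tissue_specific": ts, "n": n}, fh, indent=1)

    pairs = _ppi_pairs_from_tsv(outdir)
    summary = {"n_ppi_pairs": len(pairs)}
    if pairs:
        # genes carrying a peak: promoter overlaps an H3K4me3 or RNAPII peak
        peaks = cio.read_bed(cfg.h3k4me3) + cio.read_bed(cfg.rnapii)
        promoters = _load_promoters(outdir)
        from .core import GenomeIndex

        peak_idx = GenomeIndex.from_intervals([p.region for p in peaks])
        peak_genes = {p.gene_id for p in promoters if peak_idx.any_overlap(p.region)}
        null_a = coex.matched_random_pairs(
            pairs, genes, "A", n_bins=cfg.coexpression_bins,
            reps=cfg.coexpression_reps, seed=seed,
        )
        null_b = coex.matched_random_pairs(
            pairs, genes, "B", peak_gene_ids=peak_genes,
            n_bins=cfg.coexpression_bins, reps=cfg.coexpression_reps, seed=seed + 1,
        )
        res = coex.coexpression_test(pairs, {"A": null_a, "B": null_b}, expr)
        summary.update(
            {
                "mean_observed_r": res.mean_observed,
                "mean_diff": res.mean_diff,
                "t_p": res.t_p,
                "empirical_p": res.empirical_p,
            }
        )
    with open(outdir / "coexpression_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    _provenance(
        outdir, "coexpress",
        {"expressed_threshold": cfg.expressed_threshold, "cv_top_n": cfg.cv_top_n,
         "coexpression_bins": cfg.coexpression_bins, "coexpression_reps": cfg.coexpression_reps},
        [cfg.expression, cfg.genes, outdir / "loop_classes.tsv"],
        seed,
    )


def stage_qtl(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    genes = cio.read_gff3(cfg.genes)
    promoters = _load_promoters(outdir)
    des = _load_distal_elements(outdir)
    loops = cio.read_bedpe_loops(outdir / "loops.bedpe")
    eqtls = cio.read_association_table(cfg.eqtls)
    chrom_lengths = _read_chrom_sizes(cfg.chrom_sizes)

    labels, counts = qt.annotate_snps(
        [(e.snp_chrom, e.snp_pos) for e in eqtls], promoters, des, genes
    )
    looped = qt.eqtl_loop_overlap(eqtls, loops, promoters, cfg.snp_window)
    pd.DataFrame(
        [(p.eqtl.snp_chrom, p.eqtl.snp_pos, p.eqtl.gene_id, p.eqtl.kind) for p in looped],
        columns=["snp_chrom", "snp_pos", "gene_id", "kind"],
    ).to_csv(outdir / "eqtl_loop_pairs.tsv", sep="\t", index=False)

    calls = qt.classify_eqtl_genes(
        eqtls, looped, loops, promoters, genes, cfg.snp_window, seed=seed
    )
    pd.Series(calls.categories, name="category").rename_axis("gene_id").sort_index().to_csv(
        outdir / "eqtl_gene_categories.tsv", sep="\t"
    )

    enrich = qt.simulate_loops_null(
        loops, chrom_lengths, eqtls, promoters, cfg.snp_window,
        reps=cfg.qtl_sim_reps, seed=seed + 1,
    )
    summary = {
        "snp_annotation": counts,
        "n_looped_pairs": len(looped),
        "eqtl_enrichment": {
            "observed": enrich.observed,
            "null_mean": float(enrich.null_values.mean()),
            "empirical_p": enrich.empirical_p,
            "t_p": enrich.t_p,
            "effect": enrich.effect,
        },
    }

    if cfg.gwas:
        gwas = cio.read_gwas_table(cfg.gwas)
        de_classes = {}
        classes_path = outdir / "element_classes.tsv"
        if classes_path.exists():
            de_classes = pd.read_csv(classes_path, sep="\t", index_col=0)["class"].to_dict()
        interacting = set(de_classes)
        gres = qt.gwas_element_enrichment(
            des, interacting, gwas, chrom_lengths, cfg.gwas_window,
            random_region_reps=cfg.qtl_sim_reps, seed=seed + 2,
        )
        r = gres["interacting"]
        summary["gwas_enrichment"] = {
            "interacting_hit_rate": r.observed,
            "non_interacting_hit_rate": gres["non_interacting_rate"],
            "random_mean_hit_rate": float(r.null_values.mean()),
            "empirical_p": r.empirical_p,
            "t_p": r.t_p,
        }

    if cfg.expression:
        expr = cio.read_expression_matrix(cfg.expression)
        dists, pmat = qt.category_correlation_contrast(eqtls, looped, calls, expr)
        summary["category_correlations"] = {
            k: {"n": int(v.size), "median_r": (float(np.median(v)) if v.size else None)}
            for k, v in dists.items()
        }
        pmat.to_csv(outdir / "category_correlation_pvalues.tsv", sep="\t")

    with open(outdir / "qtl_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    _provenance(
        outdir, "qtl",
        {"snp_window": cfg.snp_window, "gwas_window": cfg.gwas_window,
         "qtl_sim_reps": cfg.qtl_sim_reps},
        [cfg.eqtls, cfg.gwas, cfg.expression, outdir / "loops.bedpe"],
        seed,
    )


_STAGE_FUNCS = {
    "elements": stage_elements,
    "loops": stage_loops,
    "classify": stage_classify,
    "coexpress": stage_coexpress,
    "qtl": stage_qtl,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Validate, then execute the requested stages in dependency order."""
    cfg.validate()
    outdir = cio.ensure_dir(cfg.outdir)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(cfg.seed)
    cfg.to_yaml(outdir / "config_used.yaml")
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            log.info("stage %s starting", stage)
            try:
                _STAGE_FUNCS[stage](cfg, outdir, seeds[stage])
            except Exception as exc:
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            log.info("stage %s done", stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
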