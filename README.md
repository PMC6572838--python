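# chialoop

Downstream analysis of promoter-centric chromatin interaction (ChIA-PET)
data in plant genomes: from paired-end tags and epigenomic tracks to
annotated regulatory elements, classified chromatin loops, co-expression
statistics and eQTL/GWAS integration.

## Who this is for

ChIA-PET (and related proximity-ligation assays against a mark such as
H3K4me3 or RNA polymerase II) yields paired-end tags (PETs) whose two ends
mark physically contacting loci. After alignment and deduplication, the
questions a regulatory genomicist asks are downstream ones:

- Which genomic segments are **promoter-proximal regions** and which are
  candidate **distal regulatory elements** (MNase-hypersensitive, hypomethylated,
  outside genes and promoters)?
- Which PET clusters are **chromatin loops**, and is each loop a
  promoter–promoter interaction (**PPI**) or a promoter–distal interaction
  (**PDI**)?
- Are loop-joined gene pairs **co-expressed** beyond what genomic distance
  alone predicts?
- Do loops connect **eQTL SNPs** to their expression-trait genes, and are
  loop-involved distal elements enriched near **GWAS/QTL** signals, beyond
  permutation nulls?

`chialoop` implements this pipeline as a tested, reusable library with a thin
CLI, plus a synthetic-data generator that plants every kind of signal with a
ground-truth manifest, so each stage can be validated for precision and
recall before touching real data.

## The methods in brief

- **Promoter-proximal regions**: strand-oriented windows `[TSS − 2 kb, TSS + 1.5 kb)`.
- **LUMRs** (low and unmethylated methylation regions): 200-bp bins whose
  coverage-weighted mean methylation satisfies `mCG < 0.2`, `mCHG < 0.1`,
  `mCHH < 0.1` (strict), adjacent passing bins merged.
- **Distal elements**: heavy-digest MNase peaks minus light-digest peaks,
  excluding anything overlapping a gene body, a gene ± 2 kb, or an H3K4me3
  peak, and requiring ≥ 1 bp overlap with a LUMR.
- **PETs and loops**: PETs are split into self-ligation (span < 8 kb),
  inter-ligation and interchromosomal. Inter-ligation tags extended ± 500 bp
  are unioned into anchors; an anchor pair becomes a loop when its PET count
  is ≥ 3 and at least one anchor overlaps a ChIP peak. Contact matrices are
  distance-normalized as observed/expected per diagonal.
- **Classification**: PPI ⇔ the two anchors overlap promoters of different
  genes; PDI ⇔ promoter on one anchor, distal element on the other; genes are
  anchor / basal (peak, no loop) / other; distal elements are single vs
  multiple by the number of distinct PDI target genes.
- **Co-expression**: Pearson *r* across tissues of loop-joined gene pairs
  versus (A) random same-chromosome pairs and (B) pairs matched on genomic
  distance (20 equal-width bins of log distance) and peak status, with a
  two-sample *T*-test and an add-one empirical *p* over replicate null means.
- **QTL integration**: an eQTL–gene pair is "looped" when one anchor overlaps
  a 4-kb window centered on the top SNP and the other overlaps the gene's
  promoter; significance comes from re-placing loops uniformly on their own
  chromosome with spans and anchor widths preserved. Distal elements are
  scanned against 200-kb windows centered on GWAS SNPs versus
  non-interacting elements and length-matched random regions.

## Worked example

Generate a synthetic bundle (one 10-Mb chromosome, 300 genes, 50 planted
loops, 20 planted LUMRs, ~1000 noise PETs, 79 expression tissues, planted
looped-pair correlation 0.6) and run every stage:

```python
from chialoop import SyntheticConfig, generate_bundle, PipelineConfig, run_pipeline

bundle = generate_bundle(SyntheticConfig(seed=7))
paths = bundle.write("demo/bundle")
cfg = PipelineConfig(
    genes=paths["genes"], h3k4me3=paths["h3k4me3"], rnapii=paths["rnapii"],
    mnase_heavy=paths["mnase_heavy"], mnase_light=paths["mnase_light"],
    methylation=paths["methylation"], pets=paths["pets"],
    expression=paths["expression"], eqtls=paths["eqtls"], gwas=paths["gwas"],
    chrom_sizes=paths["chrom_sizes"], outdir="demo/run",
    coexpression_reps=100, qtl_sim_reps=500, seed=7,
)
run_pipeline(cfg)
```

The same run from the shell: `chialoop synth --seed 7 --out demo/bundle`
followed by `chialoop all --config pipeline.yaml`.

`demo/run/` then contains BED/BEDPE/TSV/JSON outputs with per-stage
provenance blocks. Key numbers from this exact run:

- `loops_summary.json`: 1102 inter-ligation and 287 self-ligation PETs; 50
  loops called, all intrachromosomal, median span 54.1 kb.
- `coexpression_summary.json`: mean observed pair *r* = 0.581 over 30 PPI
  gene pairs; difference versus the distance-matched null B = 0.571
  (the planted correlation is 0.6), *T*-test p ≈ 8 × 10⁻²⁶, empirical
  p = 0.0099.
- `qtl_summary.json`: all 30 eQTL SNPs fall in promoter-proximal space; 12
  eQTL–gene pairs are looped versus 0.024 expected under the shuffled-loop
  null (empirical p = 0.002); interacting distal elements hit GWAS windows at
  rate 0.67 versus 0.26 for random regions (empirical p = 0.006); the median
  expression correlation of eQTL-interacting genes with looped genes is 0.62
  versus 0.02 for distance-matched random genes.

Each number reflects the planted ground truth recorded in
`demo/bundle/manifest.json`.

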