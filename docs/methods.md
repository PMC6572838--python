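# Methods

This note documents the models and procedures `chialoop` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the problem was
genuinely open.

## Coordinate model

All internal coordinates are 0-based half-open (BED convention). GFF3 input
and output is the single place a 1-based inclusive shift is applied. Overlap
everywhere means ≥ 1 bp of shared ground on half-open intervals; a
`min_overlap` parameter generalizes this where subtraction semantics matter.
Loop and PET anchors are stored in canonical order — (chrom, start, end)
with lexicographic chromosome tie-break — so deduplication, merging and
set comparisons are deterministic.

## Regulatory-element annotation

**Promoter-proximal regions** are strand-oriented TSS windows, by default
2,000 bp upstream and 1,500 bp downstream, clipped at chromosome bounds.
For a minus-strand gene the window is mirrored so "upstream" always points
away from the gene body. Unstranded gene models are rejected: without a
strand the window cannot be oriented.

**LUMR calling.** The genome is tiled in non-overlapping bins (default
200 bp). Within a bin, the level of each cytosine context is the
coverage-weighted mean Σn_meth / Σn_total over sites with total coverage
≥ 3 reads (the `min_coverage` knob); the weighted mean matches the site-level
definition of methylation as unconverted reads over total reads. A bin
passes when every *covered* context is strictly below its threshold
(CG < 0.2, CHG < 0.1, CHH < 0.1 by default — strict inequalities). A context
with no covered site imposes no constraint; a bin with no covered site in
any context is not callable and is never emitted. Adjacent passing bins are
merged into one region, reported with the weighted mean levels of the merged
region. The tests assert exact agreement with an independent per-bin scan
oracle on random tables.

**Distal elements.** Candidates are heavy-digest MNase peaks with no ≥ 1 bp
overlap with any light-digest peak — set subtraction on peak sets, not
signal-level subtraction, because the inputs are peak calls. Candidates are
then excluded if they overlap any gene body, any gene body ± 2 kb
(symmetric; strand-specific flanks are not used), or any H3K4me3 peak, and
retained only if they overlap at least one LUMR. The four rules are pure set
filters and commute; order independence is asserted in tests.

**TSS signal profiles and chromatin states.** Coverage tracks binned at
50 bp are sampled in a fixed window (default ± 3 kb) around each TSS;
minus-strand rows are flipped so upstream is always left, and bins falling
off the chromosome are reported missing (NaN), not zero. States are k-means
clusters (default k = 15) over the concatenated per-mark profile matrices,
with k-means++ initialization, 10 restarts, a fixed seed, and cluster ids
relabeled by descending cluster size so labels are stable.

## PET processing and loop calling

PETs are partitioned by the genomic span between tag midpoints:
different chromosomes → interchromosomal; span < 8 kb → self-ligation
(two ends of one fragment); otherwise inter-ligation. The 8-kb cut is a
conventional choice — the assay itself does not fix it — and is exposed as
`self_span_threshold`.

Loops are called from inter-ligation PETs only. Tags extended by ± 500 bp
are unioned into anchor regions (this reproduces roughly 1-kb anchors
without reimplementing a full ChIA-PET clustering tool; the extension is a
parameter). PETs are grouped by their (anchorA, anchorB) pair; a pair is
emitted when its PET count is ≥ 3 and at least one anchor overlaps a ChIP
peak of the matching mark, with `peak_support` recording both/one. Pairs
whose two tags merge into a single anchor are not loops. The caller's output
is sorted canonically and is invariant to input PET order.

Loop sets from two marks are merged by reciprocal anchor overlap: matched
loops are unified (anchors unioned, PET counts summed, source `merged`),
unmatched loops pass through.

Contact matrices bin tag midpoints at a configurable resolution
(1 Mb / 50 kb / 5 kb are the conventional set) and are distance-normalized
as observed/expected, where the expected value at distance d is the mean
count over all bin pairs at that distance; diagonals with zero mass stay 0
rather than dividing by zero. After normalization every distance class with
mass has mean exactly 1, which the tests assert.

## Interaction classes

A loop is **PPI** when a cross-anchor pair of *different* genes exists among
the promoters overlapping its two anchors; two anchors inside one gene's
promoter do not qualify. **PDI** requires a promoter on one anchor and a
distal element on the other. When both configurations hold, PPI takes
precedence so labels remain a partition; `dual_labels=True` records both.
Gene categories form a second partition: anchor (promoter overlaps a loop
anchor), basal (H3K4me3 or RNAPII peak but no loop), other. Distal elements
in PDIs are "single" or "multiple" by the number of *distinct* target genes,
not the number of loops.

The PPI network is an undirected gene graph with one edge per looped gene
pair (maximum PET count kept when several loops join the same pair).
Subnetworks are connected components of the subgraph restricted to edges
with PET count strictly greater than 4, ranked by size with a lexicographic
tie-break. Anchor vs non-anchor peak intensity is compared with the
two-sided Mann–Whitney rank-sum test (the two groups are independent peaks).

## Co-expression against distance-matched nulls

Expression breadth counts tissues with FPKM strictly above 1. CV = SD/mean
uses the sample (n − 1) SD; a population-SD flag exists. Genes are ranked by
ascending CV with a gene-id tie-break; the lowest-CV n genes are reported as
housekeeping and the highest-CV n as tissue-specific (stably expressed genes
have low CV by definition).

Pair correlations are Pearson *r* across tissues computed on log2(FPKM + 1);
FPKM spans orders of magnitude and the log stabilizes the statistic (a raw
scale flag exists). Gene-pair distance is TSS-to-TSS. The null controls:

- **Mode A** — random same-chromosome pairs, one per observed pair.
- **Mode B** — the observed log distances are cut into 20 equal-width bins;
  each null pair is drawn with its distance in the same bin as its observed
  counterpart and with both genes carrying an H3K4me3 or RNAPII peak (either
  mark; mark identity is not matched). Pairs identical to any observed pair
  are rejected and resampled; the per-bin pair counts of every replicate
  therefore equal the observed histogram exactly. A bin with no eligible
  pair after a bounded number of attempts raises an error naming the bin.

The headline test is a two-sided Welch *T*-test of observed *r* against the
pooled null *r*; per-replicate null means additionally give an add-one
empirical p-value, (1 + #{null mean ≥ observed mean}) / (reps + 1). The
natural-log base of the distance bins is immaterial because the bins are
equal-width on the log scale.

## eQTL and GWAS integration

SNPs are assigned one category with precedence promoter_proximal >
distal_element > gene_body > intergenic, making the annotation a partition.
A "4-kb window centered on the SNP" is read literally as SNP ± 2,000 bp,
half-open; the GWAS scan window is SNP ± 100 kb. Both are configurable.

An eQTL–etrait pair is *looped* when one anchor of a loop overlaps the SNP
window and the other anchor overlaps the etrait gene's promoter. Genes then
classify as: eqtl_gene (associated, not looped), looped_gene (associated and
looped), eqtl_interacting_gene (not associated, but its promoter sits at the
anchor across a loop from an eQTL window), plus distance-matched random
controls drawn from non-associated, non-looped genes at a similar TSS-to-SNP
distance (± 50% tolerance with nearest-distance fallback). Trans
associations participate only when SNP and gene share a chromosome, since
only intra-chromosomal loops are tested by default.

The loop-shuffle null re-places each intra-chromosomal loop uniformly on its
own chromosome, preserving both anchor widths and the anchor offset (hence
the span) exactly; the sampling range makes clipped placements impossible.
The GWAS null places chromosome- and length-matched random regions uniformly
per replicate. Both nulls report the add-one empirical p — which cannot be
zero and is conservative under ties — alongside a one-sample *T*-test of the
null distribution against the observed value. Whether a shuffled loop
retains anchor–peak support is deliberately not preserved; the null models
position, not peak architecture.

Expression contrasts between gene categories pair genes through their shared
SNP locus (five pairings: eqtl:eqtl, eqtl:loop, eqtl_interacting:loop,
random:loop, random:eqtl_interacting), exclude self-pairs, and compare
pairings with two-sided rank-sum tests.

## Synthetic data: what it emulates and what it does not

The generator plants, on one or more uniform-length chromosomes:
non-overlapping genes (rejection sampling with a minimum gap, default 6 kb,
which keeps promoter and flank exclusions unambiguous); H3K4me3 and RNAPII
peaks at a configurable fraction of promoters; PPI loop groups between
peaked promoters with spans in 10–100 kb (the typical loop-span range);
distal elements in intergenic space with PDI loops to promoters, a quarter
of the PDI budget spent on two-target ("multiple") elements; grid-aligned
hypomethylated blocks (one under each element, the rest elsewhere);
per-cytosine methylation on a dense site grid (spacing 10 bp, interleaved
CG/CHG/CHH contexts as all three co-occur at fine scale in real genomes,
beta-distributed site levels around context means — background
CG 0.8 / CHG 0.6 / CHH 0.05, blocks 0.02/0.01/0.01 with a tight
concentration so planted blocks stay below the calling thresholds under
binomial read sampling); ≥ 3 supporting PETs per loop with jittered tags
plus uniform noise PETs with log-uniform spans (defaults give ~1,000 noise
PETs against ~400 planted ones); a 79-tissue FPKM matrix in which each loop
group shares a latent tissue factor, x = √bg·z₀ + √(ρ−bg)·z_group +
√(1−ρ)·ε and FPKM = exp(μ + 0.8x), so the pairwise Pearson correlation of
looped genes is ≈ ρ (default 0.6) on the log scale against background bg
(default 0); eQTLs whose linked fraction sits at a loop-group hub — the SNP
at the hub TSS, the etrait gene across one loop (a looped gene) and a second
partner across another loop (an eQTL-interacting gene, sharing the group's
expression factor); and GWAS SNPs placed near interacting elements for a
configured fraction. Anchor-gene peaks get a 2× intensity boost, emulating
the brighter ChIP signal of interaction anchors. Every planted object is
recorded in a JSON manifest, and identical (config, seed) yields a
byte-identical bundle.

Not emulated: sequence-level artifacts (reads, linkers, bisulfite
conversion), realistic karyotypes or chromosome-scale heterogeneity,
overlapping genes and nested transcripts, peak-calling noise, batch effects
across tissues, and trans-eQTL architecture. Passing the planted-truth
suites therefore demonstrates correctness of the downstream logic under
clean, well-separated signals — not performance on noisy real libraries,
where anchor merging, borderline methylation and peak-call errors will
degrade precision and recall.

## Problem sizes used by the test and acceptance runs

The default bundle is one 10-Mb chromosome with 300 genes, 50 loops,
20 LUMRs and ~1,000 noise PETs. The co-expression effect-size check uses a
25-Mb chromosome with 700 genes and 220 planted pairs across 79 tissues.
Null-calibration suites run 200 simulated datasets per test with reduced
replicate counts (10–39 permutations per dataset); the add-one estimator
keeps these conservative. The acceptance script uses 500 permutation
replicates for both enrichments and 20 replicates for the matched
co-expression null. These sizes are the package's chosen study conditions;
all scale linearly through configuration.

## Known limitations

- The anchor construction (tag extension + union) approximates dedicated
  ChIA-PET clustering; very dense tag fields can chain anchors together.
- The LUMR caller reports only bins with methylation coverage; genuinely
  unmethylated but unassayed regions are invisible to it.
- Empirical p-values are bounded below by 1/(reps + 1); strong enrichments
  need large replicate counts to show small p.
- `category_correlation_contrast` pairs genes through shared SNP loci; lone
  eQTLs contribute no pairs, so some pairings can be empty on sparse inputs.
- The distance-matched random-gene draw for eQTL controls uses a ± 50%
  distance tolerance rather than exact binning when candidates are sparse.
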