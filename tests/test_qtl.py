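"""SNP annotation, eQTL-loop overlap, gene categories, enrichment nulls."""

import numpy as np
import pytest

from chialoop import qtl as qt
from chialoop.core import EqtlAssociation, GeneModel, GenomicInterval, GwasSnp, Loop
from chialoop.elements import DistalElement, PromoterRegion

from oracles import brute_snp_annotation


def prom(gene_id, chrom, start, end):
    return PromoterRegion(GenomicInterval(chrom, start, end), gene_id)


def de(eid, chrom, start, end):
    return DistalElement(GenomicInterval(chrom, start, end), eid, ())


def loop(chrom, a_start, b_start, width=1000):
    return Loop(
        GenomicInterval(chrom, a_start, a_start + width),
        GenomicInterval(chrom, b_start, b_start + width),
    )


class TestAnnotateSnps:
    @pytest.fixture()
    def annotation(self):
        genes = [GeneModel("g1", GenomicInterval("chr1", 10_000, 15_000, "+"))]
        promoters = [prom("g1", "chr1", 8_000, 11_500)]
        elements = [de("d1", "chr1", 40_000, 40_600)]
        return promoters, elements, genes

    def test_promoter_precedence_over_gene_body(self, annotation):
        promoters, elements, genes = annotation
        labels, _ = qt.annotate_snps([("chr1", 10_500)], promoters, elements, genes)
        assert labels == ["promoter_proximal"]  # inside both promoter and body

    def test_intergenic_default(self, annotation):
        promoters, elements, genes = annotation
        labels, counts = qt.annotate_snps([("chr1", 900_000)], promoters, elements, genes)
        assert labels == ["intergenic"] and counts["intergenic"] == 1

    def test_twenty_snp_fixture_matches_hand_annotation(self, annotation):
        promoters, elements, genes = annotation
        rng = np.random.default_rng(0)
        snps = [("chr1", int(p)) for p in rng.integers(0, 60_000, 20)]
        labels, counts = qt.annotate_snps(snps, promoters, elements, genes)
        expected = brute_snp_annotation(
            snps,
            [("chr1", 8_000, 11_500)],
            [("chr1", 40_000, 40_600)],
            [("chr1", 10_000, 15_000)],
        )
        assert labels == expected
        assert sum(counts.values()) == 20  # total partition

    def test_partition_on_bundle(self, pipeline_results):
        b = pipeline_results.bundle
        snps = [(e.snp_chrom, e.snp_pos) for e in b.eqtls]
        labels, counts = qt.annotate_snps(
            snps, pipeline_results.promoters, pipeline_results.distal_elements, b.genes
        )
        assert sum(counts.values()) == len(snps)
        # planted SNPs sit at gene TSSs, i.e. in promoter-proximal space
        assert counts["promoter_proximal"] == len(snps)


class TestEqtlLoopOverlap:
    def scene(self, snp_offset):
        """A loop anchored at [50_000, 51_000) and the etrait promoter at anchorB."""
        lo = loop("chr1", 50_000, 150_000)
        promoters = [prom("gT", "chr1", 149_500, 153_000)]
        snp_pos = 50_000 - snp_offset  # left of anchor edge
        eqtl = EqtlAssociation("chr1", snp_pos, "gT", "cis")
        return [eqtl], [lo], promoters

    def test_snp_1500bp_from_anchor_edge_counted(self):
        eqtls, loops, promoters = self.scene(1500)
        assert len(qt.eqtl_loop_overlap(eqtls, loops, promoters, 4000)) == 1

    def test_snp_2500bp_from_anchor_edge_not_counted(self):
        eqtls, loops, promoters = self.scene(2500)
        assert qt.eqtl_loop_overlap(eqtls, loops, promoters, 4000) == []

    def test_planted_links_recovered_exactly(self, pipeline_results):
        truth = {
            (e["snp_chrom"], e["snp_pos"], e["gene_id"])
            for e in pipeline_results.bundle.manifest.eqtls
            if e["loop_linked"]
        }
        found = {
            (p.eqtl.snp_chrom, p.eqtl.snp_pos, p.eqtl.gene_id)
            for p in pipeline_results.looped_pairs
        }
        assert found == truth


class TestClassifyEqtlGenes:
    def test_categories_and_disjointness(self, pipeline_results):
        b = pipeline_results.bundle
        calls = qt.classify_eqtl_genes(
            b.eqtls, pipeline_results.looped_pairs, pipeline_results.loops,
            pipeline_results.promoters, b.genes, seed=0,
        )
        cats = calls.categories
        by_cat = {}
        for gid, c in cats.items():
            by_cat.setdefault(c, set()).add(gid)
        non_random = [qt.EQTL_GENE, qt.LOOPED_GENE, qt.EQTL_INTERACTING_GENE]
        for i, a in enumerate(non_random):
            for b2 in non_random[i + 1:]:
                assert not (by_cat.get(a, set()) & by_cat.get(b2, set()))
        # planted: looped genes are the linked etraits; interacting genes are
        # their loop partners
        truth_linked = {e["gene_id"] for e in b.manifest.eqtls if e["loop_linked"]}
        truth_inter = {e["interacting_gene"] for e in b.manifest.eqtls if e["loop_linked"]}
        assert by_cat.get(qt.LOOPED_GENE, set()) == truth_linked
        assert by_cat.get(qt.EQTL_INTERACTING_GENE, set()) == truth_inter

    def test_non_associated_looped_gene_is_interacting(self):
        # gX's promoter sits at the anchor across the loop from the SNP window
        lo = loop("chr1", 50_000, 150_000)
        promoters = [prom("gT", "chr1", 149_500, 153_000),
                     prom("gX", "chr1", 150_200, 153_700)]
        genes = [GeneModel("gT", GenomicInterval("chr1", 151_500, 155_000, "+")),
                 GeneModel("gX", GenomicInterval("chr1", 152_200, 156_000, "+")),
                 GeneModel("gZ", GenomicInterval("chr1", 500_000, 504_000, "+"))]
        eqtl = EqtlAssociation("chr1", 50_500, "gT", "cis")
        looped = qt.eqtl_loop_overlap([eqtl], [lo], promoters, 4000)
        calls = qt.classify_eqtl_genes([eqtl], looped, [lo], promoters, genes, seed=1)
        assert calls.categories["gT"] == qt.LOOPED_GENE
        assert calls.categories["gX"] == qt.EQTL_INTERACTING_GENE


class TestSimulatedLoopNull:
    def test_shuffle_preserves_spans_and_widths(self, pipeline_results):
        rng = np.random.default_rng(0)
        loops = pipeline_results.loops
        lengths = pipeline_results.bundle.chrom_lengths
        for _ in range(5):
            shuffled = qt.shuffle_loops(loops, lengths, rng)
            for orig, new in zip(loops, shuffled):
                assert new.span == orig.span
                assert new.anchorA.width == orig.anchorA.width
                assert new.anchorB.width == orig.anchorB.width
                assert new.anchorA.chrom == orig.anchorA.chrom
                assert 0 <= new.anchorA.start and new.anchorB.end <= lengths[new.anchorA.chrom]

    def test_oversized_loop_rejected(self):
        lo = loop("chr1", 0, 9_000_000)
        with pytest.raises(ValueError, match="extent"):
            qt.shuffle_loops([lo], {"chr1": 1_000_000}, np.random.default_rng(0))

    def test_planted_enrichment_detected(self, pipeline_results):
        b = pipeline_results.bundle
        res = qt.simulate_loops_null(
            pipeline_results.loops, b.chrom_lengths, b.eqtls,
            pipeline_results.promoters, reps=200, seed=3,
        )
        assert res.observed == len(pipeline_results.looped_pairs)
        assert res.empirical_p < 0.05
        assert res.effect > 5


class TestGwasEnrichment:
    def window_scene(self, distance):
        element = de("d1", "chr1", 1_000_000, 1_000_500)
        snp = GwasSnp("chr1", 1_000_250 + distance, "trait")
        return [element], [snp]

    def test_element_90kb_from_snp_counted(self):
        elements, snps = self.window_scene(90_000)
        res = qt.gwas_element_enrichment(
            elements, {"d1"}, snps, {"chr1": 10_000_000}, window=200_000,
            random_region_reps=2, seed=0,
        )
        assert res["interacting"].observed == 1.0

    def test_element_150kb_from_snp_not_counted(self):
        elements, snps = self.window_scene(150_000)
        res = qt.gwas_element_enrichment(
            elements, {"d1"}, snps, {"chr1": 10_000_000}, window=200_000,
            random_region_reps=2, seed=0,
        )
        assert res["interacting"].observed == 0.0

    def test_planted_enrichment_detected(self, pipeline_results):
        b = pipeline_results.bundle
        res = qt.gwas_element_enrichment(
            pipeline_results.distal_elements, set(pipeline_results.element_classes),
            b.gwas_snps, b.chrom_lengths, random_region_reps=200, seed=4,
        )
        r = res["interacting"]
        assert r.observed > r.null_values.mean()
        assert r.empirical_p < 0.05


class TestCategoryCorrelations:
    def test_self_pairs_excluded_and_planted_contrast(self, pipeline_results):
        b = pipeline_results.bundle
        calls = qt.classify_eqtl_genes(
            b.eqtls, pipeline_results.looped_pairs, pipeline_results.loops,
            pipeline_results.promoters, b.genes, seed=0,
        )
        dists, pmat = qt.category_correlation_contrast(
            b.eqtls, pipeline_results.looped_pairs, calls, b.expression
        )
        # interacting genes share the looped genes' latent factor by design
        ik, rk = "eqtl_interacting:loop", "random:loop"
        assert dists[ik].size > 0 and dists[rk].size > 0
        assert np.median(dists[ik]) > np.median(dists[rk])
        assert pmat.loc[ik, rk] < 0.05

    def test_independent_expression_gives_null_medians(self):
        """With iid expression, every pairing's median r is near zero."""
        from chialoop.synth import SyntheticConfig, generate_bundle

        config = SyntheticConfig(
            chromosome_length=8_000_000, n_genes=240, n_planted_loops=40,
            ppi_fraction=1.0, pdi_fraction=0.0, n_orphan_elements=0,
            n_planted_lumrs=0, site_spacing=2000, coexpression_rho=0.0,
            n_eqtls=30, eqtl_loop_link_fraction=0.5, n_gwas_snps=0, seed=44,
        )
        b = generate_bundle(config)
        from chialoop import elements as el

        promoters = el.call_promoter_regions(b.genes, chrom_lengths=b.chrom_lengths)
        planted_loops = [
            Loop(GenomicInterval(**m["anchorA"]), GenomicInterval(**m["anchorB"]))
            for m in b.manifest.loops
        ]
        looped = qt.eqtl_loop_overlap(b.eqtls, planted_loops, promoters)
        calls = qt.classify_eqtl_genes(b.eqtls, looped, planted_loops, promoters, b.genes, seed=2)
        dists, _ = qt.category_correlation_contrast(b.eqtls, looped, calls, b.expression)
        for key, vals in dists.items():
            if vals.size >= 10:
                assert abs(np.median(vals)) < 0.15, key
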