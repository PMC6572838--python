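"""Promoter windows, LUMR calling, distal-element filters, profiles, TSS states."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chialoop import elements as el
from chialoop.core import GeneModel, GenomicInterval, MethylationCall, Peak

from oracles import brute_lumrs


def gene(gid, chrom, start, end, strand):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


class TestPromoterRegions:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [
            ("+", 100_000, 105_000, (98_000, 101_500)),
            ("-", 55_000, 60_001, (58_500, 62_000)),
            ("+", 1000, 4000, (0, 2500)),
        ],
    )
    def test_window_arithmetic(self, strand, start, end, expected):
        g = gene("g1", "chr1", start, end, strand)
        (prom,) = el.call_promoter_regions([g])
        assert (prom.region.start, prom.region.end) == expected
        assert prom.gene_id == "g1"

    def test_clipped_at_chromosome_end(self):
        g = gene("g1", "chr1", 8000, 9500, "-")  # tss = 9499
        (prom,) = el.call_promoter_regions([g], chrom_lengths={"chr1": 10_000})
        assert prom.region.end == 10_000

    def test_unstranded_gene_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            gene("g1", "chr1", 0, 100, ".")


def mk_calls(chrom, bin_start, levels, n_per_context=5, depth=20):
    """Build one 200-bp bin's worth of calls at the given context levels."""
    calls = []
    pos = bin_start
    for context, level in levels.items():
        for _ in range(n_per_context):
            calls.append(
                MethylationCall(chrom, pos, context, int(round(level * depth)), depth)
            )
            pos += 3
    return calls


class TestLumrs:
    def test_bin_below_all_thresholds_passes(self):
        calls = mk_calls("chr1", 1000, {"CG": 0.15, "CHG": 0.05, "CHH": 0.03})
        (lumr,) = el.call_lumrs(calls)
        assert (lumr.region.start, lumr.region.end) == (1000, 1200)

    def test_cg_exactly_at_threshold_fails(self):
        # strict inequality: CG weighted mean exactly 0.2 is not low-methylated
        calls = mk_calls("chr1", 1000, {"CG": 0.2, "CHG": 0.05, "CHH": 0.03})
        assert el.call_lumrs(calls) == []

    def test_uncovered_context_imposes_no_constraint(self):
        calls = mk_calls("chr1", 0, {"CG": 0.1, "CHG": 0.05})
        assert len(el.call_lumrs(calls)) == 1

    def test_low_coverage_sites_ignored(self):
        bad = [MethylationCall("chr1", 10, "CG", 2, 2)]  # below min_coverage
        good = mk_calls("chr1", 0, {"CG": 0.1, "CHG": 0.02, "CHH": 0.01})
        (lumr,) = el.call_lumrs(bad + good, min_coverage=3)
        assert lumr.mean_levels[0] < 0.2

    def test_adjacent_bins_merge(self):
        calls = mk_calls("chr1", 0, {"CG": 0.1}) + mk_calls("chr1", 200, {"CG": 0.05})
        (lumr,) = el.call_lumrs(calls)
        assert (lumr.region.start, lumr.region.end) == (0, 400)

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            el.call_lumrs([], bin_size=0)

    def test_planted_blocks_recovered_on_synthetic_chromosome(self):
        """3 hypomethylated blocks on a 100-kb chromosome, vs brute-force oracle."""
        rng = np.random.default_rng(7)
        blocks = [(20_000, 20_600), (50_200, 51_000), (80_000, 80_400)]
        calls = []
        for pos in range(0, 100_000, 20):
            ctx = ["CG", "CHG", "CHH"][pos // 20 % 3]
            in_block = any(s <= pos < e for s, e in blocks)
            mean = {"CG": 0.8, "CHG": 0.6, "CHH": 0.05}[ctx] if not in_block else 0.02
            n_total = 10
            n_meth = int(rng.binomial(n_total, mean))
            calls.append(MethylationCall("chr1", pos, ctx, n_meth, n_total))
        got = [(l.region.chrom, l.region.start, l.region.end) for l in el.call_lumrs(calls)]
        assert got == brute_lumrs(calls)
        assert [(s, e) for _, s, e in got] == blocks

    def test_matches_brute_force_on_random_tables(self):
        """Property: vectorized caller agrees with the per-bin scan oracle."""
        rng = np.random.default_rng(42)
        contexts = ["CG", "CHG", "CHH"]
        for trial in range(100):
            n = int(rng.integers(20, 200))
            calls = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                pos = int(rng.integers(0, 4000))
                ctx = contexts[rng.integers(3)]
                n_total = int(rng.integers(1, 30))
                n_meth = int(rng.integers(0, n_total + 1))
                calls.append(MethylationCall(chrom, pos, ctx, n_meth, n_total))
            got = [(l.region.chrom, l.region.start, l.region.end)
                   for l in el.call_lumrs(calls)]
            assert got == brute_lumrs(calls), f"trial {trial}"


def peak(chrom, start, end, mark="MNase_heavy", name=""):
    return Peak(GenomicInterval(chrom, start, end), 1.0, mark, name)


class TestDistalElements:
    @pytest.fixture()
    def scene(self):
        genes = [gene("g1", "chr1", 50_000, 55_000, "+")]
        k4 = [peak("chr1", 30_000, 31_000, "H3K4me3")]
        lumr_regions = [
            el.Lumr(GenomicInterval("chr1", s, e), (0.1, 0.05, 0.05))
            for s, e in [(10_000, 10_600), (20_000, 20_600), (40_000, 40_600),
                         (70_000, 70_600), (90_000, 90_600)]
        ]
        light = [peak("chr1", 9_900, 10_100, "MNase_light")]
        return genes, k4, lumr_regions, light

    def test_hand_enumerated_filtering(self, scene):
        genes, k4, lumrs, light = scene
        heavy = [
            peak("chr1", 10_000, 10_400, name="h0"),   # overlaps light -> out
            peak("chr1", 20_100, 20_500, name="h1"),   # survives
            peak("chr1", 30_200, 30_600, name="h2"),   # overlaps H3K4me3 -> out
            peak("chr1", 40_100, 40_500, name="h3"),   # survives
            peak("chr1", 51_000, 51_400, name="h4"),   # inside gene body -> out
            peak("chr1", 54_000, 56_500, name="h5"),   # overlaps body end -> out
            peak("chr1", 56_000, 56_400, name="h6"),   # within 2 kb of gene -> out
            peak("chr1", 70_100, 70_500, name="h7"),   # survives
            peak("chr1", 80_000, 80_400, name="h8"),   # no LUMR -> out
            peak("chr1", 95_000, 95_400, name="h9"),   # no LUMR -> out
        ]
        out = el.call_distal_elements(heavy, light, genes, k4, lumrs)
        assert [d.source_peak_id for d in out] == ["h1", "h3", "h7"]

    def test_one_bp_light_overlap_excludes(self, scene):
        genes, k4, lumrs, light = scene
        # heavy ends exactly where light starts +1 bp of shared ground
        heavy = [peak("chr1", 9_500, 9_901, name="h")]
        assert el.call_distal_elements(heavy, light, genes, k4, lumrs) == []
        heavy = [peak("chr1", 9_500, 9_900, name="h")]  # book-ended: 0 bp shared
        # still dropped only if it overlapped a LUMR requirement-wise; no LUMR here
        assert el.call_distal_elements(heavy, [], genes, k4, lumrs) == []

    def test_one_kb_from_gene_excluded(self, scene):
        genes, k4, lumrs, _ = scene
        # 1 kb downstream of the gene body: inside the 2-kb flank
        heavy = [peak("chr1", 56_000, 56_300, name="h")]
        assert el.call_distal_elements(heavy, [], genes, k4, lumrs) == []

    def test_filters_are_order_independent(self, scene):
        import itertools

        genes, k4, lumrs, light = scene
        heavy = [peak("chr1", s, s + 400, name=f"h{s}")
                 for s in (10_000, 20_100, 30_200, 40_100, 56_000, 80_000)]

        def as_sets():
            light_iv = [p.region for p in light]
            k4_iv = [p.region for p in k4]
            flank_iv = [GenomicInterval(g.chrom, g.body.start - 2000, g.body.end + 2000)
                        for g in genes]
            lumr_iv = [l.region for l in lumrs]

            def overlaps_any(r, ivs):
                return any(r.overlaps(iv) for iv in ivs)

            filters = {
                "light": lambda r: not overlaps_any(r, light_iv),
                "flank": lambda r: not overlaps_any(r, flank_iv),
                "k4": lambda r: not overlaps_any(r, k4_iv),
                "lumr": lambda r: overlaps_any(r, lumr_iv),
            }
            results = set()
            for order in itertools.permutations(filters):
                kept = frozenset(
                    p.name for p in heavy if all(filters[f](p.region) for f in order)
                )
                results.add(kept)
            return results

        all_orders = as_sets()
        assert len(all_orders) == 1
        got = {d.source_peak_id for d in el.call_distal_elements(heavy, light, genes, k4, lumrs)}
        assert got == next(iter(all_orders))

    def test_empty_heavy_list_gives_empty_result(self, scene):
        genes, k4, lumrs, light = scene
        assert el.call_distal_elements([], light, genes, k4, lumrs) == []

    def test_emitted_elements_satisfy_invariants(self, pipeline_results):
        b = pipeline_results.bundle
        flanks = [GenomicInterval(g.chrom, max(0, g.body.start - 2000), g.body.end + 2000)
                  for g in b.genes]
        k4 = [p.region for p in b.h3k4me3_peaks]
        lumr_iv = [l.region for l in pipeline_results.lumrs]
        for d in pipeline_results.distal_elements:
            assert not any(d.region.overlaps(iv) for iv in flanks)
            assert not any(d.region.overlaps(iv) for iv in k4)
            assert any(d.region.overlaps(iv) for iv in lumr_iv)


class TestSignalProfile:
    def test_constant_track(self):
        cov = {"chr1": np.full(200, 3.5)}
        prof = el.signal_profile([("r1", "chr1", 5000, "+")], cov, flank=500, bin=50)
        assert (prof.loc["r1"] == 3.5).all()

    def test_chromosome_edge_is_missing_not_zero(self):
        cov = {"chr1": np.ones(100)}
        prof = el.signal_profile([("r1", "chr1", 100, "+")], cov, flank=500, bin=50)
        row = prof.loc["r1"]
        assert row.isna().sum() == 8  # bins before position 0
        assert (row.dropna() == 1.0).all()

    def test_minus_strand_summit_flipped(self):
        cov = {"chr1": np.zeros(400)}
        tss = 10_000
        cov["chr1"][(tss - 500) // 50] = 9.0  # peak 500 bp left of a minus-strand TSS
        prof = el.signal_profile([("r1", "chr1", tss, "-")], cov, flank=3000, bin=50)
        # left of a minus-strand gene is downstream; after flipping, the summit
        # sits 500 bp downstream, i.e. in the bin [450, 500)
        assert prof.loc["r1"].idxmax() == 450

    def test_flank_must_be_multiple_of_bin(self):
        with pytest.raises(ValueError):
            el.signal_profile([], {"chr1": np.zeros(1)}, flank=70, bin=50)


class TestTssStates:
    def make_profiles(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = np.tile([5.0] * 10 + [0.0] * 10, (n // 2, 1))
        b = np.tile([0.0] * 10 + [5.0] * 10, (n // 2, 1))
        X = np.vstack([a, b]) + rng.normal(0, 0.1, (n, 20))
        idx = [f"g{i}" for i in range(n)]
        truth = [0] * (n // 2) + [1] * (n // 2)
        return {"m": pd.DataFrame(X, index=idx)}, truth

    def test_two_archetypes_perfectly_separated(self):
        profiles, truth = self.make_profiles()
        labels = el.cluster_tss_states(profiles, k=2, seed=3)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_k_one_single_label(self):
        profiles, _ = self.make_profiles()
        assert set(el.cluster_tss_states(profiles, k=1, seed=0)) == {0}

    def test_same_seed_identical_labels(self):
        profiles, _ = self.make_profiles()
        l1 = el.cluster_tss_states(profiles, k=4, seed=9)
        l2 = el.cluster_tss_states(profiles, k=4, seed=9)
        assert l1.equals(l2)

    def test_k_larger_than_genes_rejected(self):
        profiles, _ = self.make_profiles(n=10)
        with pytest.raises(ValueError):
            el.cluster_tss_states(profiles, k=11, seed=0)

    def test_labels_ordered_by_cluster_size(self):
        rng = np.random.default_rng(1)
        X = np.vstack([np.full((30, 5), 10.0), np.full((10, 5), -10.0)])
        X += rng.normal(0, 0.01, X.shape)
        profiles = {"m": pd.DataFrame(X, index=[f"g{i}" for i in range(40)])}
        labels = el.cluster_tss_states(profiles, k=2, seed=0)
        assert (labels.to_numpy()[:30] == 0).all() and (labels.to_numpy()[30:] == 1).all()
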