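"""Shared fixtures: synthetic bundles and the downstream results computed on them."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from chialoop import classify as cls
from chialoop import coexpression as coex
from chialoop import elements as el
from chialoop import loops as lp
from chialoop import qtl as qt
from chialoop.synth import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 1 x 10 Mb chromosome, 300 genes,
    50 planted loops, 20 planted LUMRs, ~1000 uniform noise PETs."""
    return generate_bundle(SyntheticConfig(seed=20))


@dataclass
class PipelineResults:
    bundle: object
    promoters: list
    lumrs: list
    distal_elements: list
    loops: list
    loop_classes: list
    element_classes: dict = field(default_factory=dict)
    looped_pairs: list = field(default_factory=list)


@pytest.fixture(scope="session")
def pipeline_results(default_bundle) -> PipelineResults:
    """Full downstream chain run on the default bundle."""
    b = default_bundle
    promoters = el.call_promoter_regions(b.genes, chrom_lengths=b.chrom_lengths)
    lumrs = el.call_lumrs(b.methylation)
    des = el.call_distal_elements(
        b.mnase_heavy, b.mnase_light, b.genes, b.h3k4me3_peaks, lumrs
    )
    pets = lp.categorize_pets(b.pets)
    inter = [p for p in pets if p.category == lp.PET_INTER]
    loops = lp.call_loops(inter, b.h3k4me3_peaks + b.rnapii_peaks)
    loop_classes = cls.classify_loops(loops, promoters, des)
    element_classes = cls.classify_distal_elements(loop_classes)
    looped_pairs = qt.eqtl_loop_overlap(b.eqtls, loops, promoters)
    return PipelineResults(
        b, promoters, lumrs, des, loops, loop_classes, element_classes, looped_pairs
    )


@pytest.fixture(scope="session")
def coexpr_bundle():
    """A bundle with >= 200 planted co-expressed promoter pairs, 79 tissues.

    One 25-Mb chromosome with 700 genes gives every gene several potential
    partners inside the 10-100 kb loop-span range; methylation is thinned
    since this bundle only exercises the expression analyses.
    """
    config = SyntheticConfig(
        chromosome_length=25_000_000,
        n_genes=700,
        n_planted_loops=220,
        ppi_fraction=1.0,
        pdi_fraction=0.0,
        n_orphan_elements=0,
        n_planted_lumrs=0,
        site_spacing=2000,
        noise_pet_fraction=0.0,
        n_eqtls=0,
        n_gwas_snps=0,
        seed=21,
    )
    return generate_bundle(config)
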