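import numpy as np
import pytest

from gigsplice.genemodel import Exon, GeneModel
from gigsplice.simulate import JunctionMix, SimConfig, simulate_gene


@pytest.fixture
def plus_gene():
    """Three exons on +: [100,200), [400,500), [800,950)."""
    return GeneModel(
        gene_id="gplus",
        chromosome="chr1",
        strand="+",
        exons=[Exon(1, 100, 200), Exon(2, 400, 500), Exon(3, 800, 950)],
    )


@pytest.fixture
def minus_gene():
    """Mirror of plus_gene on -: exon 1 is the rightmost span."""
    return GeneModel(
        gene_id="gminus",
        chromosome="chr1",
        strand="-",
        exons=[Exon(1, 800, 950), Exon(2, 400, 500), Exon(3, 100, 200)],
    )


@pytest.fixture(scope="session")
def mixed_sim():
    """8-exon simulated gene with per-junction mixture variation (shared)."""
    mixes = [JunctionMix()] + [
        JunctionMix(spliced=0.70, unspliced=0.20, exon_other=0.05, backsplice=0.04, chimera=0.01),
        JunctionMix(spliced=0.85, unspliced=0.10, exon_other=0.02, backsplice=0.02, chimera=0.01),
        JunctionMix(spliced=0.55, unspliced=0.25, exon_other=0.05, backsplice=0.12, chimera=0.03),
        JunctionMix(spliced=0.90, unspliced=0.05, exon_other=0.02, backsplice=0.02, chimera=0.01),
        JunctionMix(spliced=0.75, unspliced=0.15, exon_other=0.04, backsplice=0.05, chimera=0.01),
        JunctionMix(spliced=0.60, unspliced=0.30, exon_other=0.04, backsplice=0.05, chimera=0.01),
    ]
    cfg = SimConfig(
        exon_lengths=[400] * 8,
        intron_lengths=[500, 900, 1300, 700, 1100, 600, 1500],
        mixes=mixes,
        reads_per_junction=600,
        seed=20240917,
    )
    return simulate_gene(cfg)
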