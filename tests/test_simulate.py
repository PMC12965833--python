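import io

import numpy as np
import pytest

from gigsplice.alignment import write_sam
from gigsplice.genemodel import junction_coords
from gigsplice.simulate import (
    Attenuation,
    JunctionMix,
    SimConfig,
    SizeEffect,
    exon_five_prime_comparator,
    simulate_cohort,
    simulate_gene,
)


def _basic_cfg(**kw):
    defaults = dict(
        exon_lengths=[400] * 4,
        intron_lengths=[500, 800, 600],
        reads_per_junction=200,
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGene:
    def test_pure_spliced_mix_is_degenerate(self):
        cfg = _basic_cfg(mixes=JunctionMix(), reads_per_junction=500)
        sim = simulate_gene(cfg)
        assert len(sim.reads) == 1500
        assert all(rec.category == "spliced" for rec in sim.truth.values())
        for r in sim.reads:
            j = sim.truth[r.read_id].junction_index
            donor, acceptor = junction_coords(sim.model, j)
            skips = [(op, n) for op, n in r.cigar if op == "N"]
            assert len(skips) == 1
            b0, b1 = r.blocks
            assert b0[1] == donor and b1[0] == acceptor

    def test_category_fractions_match_mix_within_3sd(self):
        mix = JunctionMix(spliced=0.7, unspliced=0.2, exon_other=0.05, backsplice=0.05)
        n = 2000
        cfg = _basic_cfg(
            mixes=[JunctionMix(), mix, mix], reads_per_junction=[0, n, n], seed=1
        )
        sim = simulate_gene(cfg)
        for j in (2, 3):
            counts = sim.truth_counts(j)
            total = sum(counts.values())
            assert total == n
            for cat, p in zip(
                ("spliced", "unspliced", "exon_other", "backsplice"),
                (0.7, 0.2, 0.05, 0.05),
            ):
                sd = np.sqrt(p * (1 - p) / n)
                assert abs(counts[cat] / n - p) <= 3 * sd, (j, cat)

    def test_attenuation_thins_downstream_junction_counts(self):
        cfg = SimConfig(
            exon_lengths=[400] * 8,
            intron_lengths=[500] * 7,
            reads_per_junction=1000,
            attenuation=Attenuation(junction_index=5, retention=0.3),
            seed=2,
        )
        sim = simulate_gene(cfg)
        for j in range(1, 8):
            total = sum(sim.truth_counts(j).values())
            if j <= 5:
                assert total == 1000
            else:
                sd = np.sqrt(1000 * 0.3 * 0.7)
                assert abs(total - 300) <= 3 * sd

    def test_same_seed_gives_byte_identical_sam_and_truth(self, tmp_path):
        outs = []
        mix = JunctionMix(0.8, 0.1, 0.05, 0.04, 0.01)
        for rep in range(2):
            sim = simulate_gene(_basic_cfg(mixes=[JunctionMix(), mix, mix]))
            path = tmp_path / f"r{rep}.sam"
            chrom, ref = next(iter(sim.reference.items()))
            write_sam(sim.reads, path, {chrom: len(ref)})
            outs.append((path.read_bytes(), sim.truth))
        assert outs[0][0] == outs[1][0]
        assert outs[0][1] == outs[1][1]

    def test_backsplice_clip_is_exact_acceptor_prefix(self):
        cfg = _basic_cfg(mixes=JunctionMix(0, 0, 0, 1.0, 0), reads_per_junction=[0, 50, 50])
        sim = simulate_gene(cfg)
        ref = sim.reference[cfg.chromosome]
        assert sim.truth
        for r in sim.reads:
            rec = sim.truth[r.read_id]
            clip = r.right_clip if sim.model.strand == "+" else r.left_clip
            expect = exon_five_prime_comparator(sim.model, ref, rec.acceptor_exon, len(clip))
            assert clip == expect

    def test_backsplice_at_first_junction_rejected(self):
        with pytest.raises(ValueError, match="earlier exon"):
            simulate_gene(_basic_cfg(mixes=JunctionMix(0.5, 0, 0, 0.5, 0)))

    def test_read_length_shorter_than_overhang_rejected(self):
        with pytest.raises(ValueError, match="read_length too short"):
            simulate_gene(_basic_cfg(read_length=10, min_overhang=6))

    def test_minus_strand_spliced_reads_hit_canonical_coordinates(self):
        cfg = _basic_cfg(strand="-", mixes=JunctionMix(), reads_per_junction=100)
        sim = simulate_gene(cfg)
        for r in sim.reads:
            j = sim.truth[r.read_id].junction_index
            donor, acceptor = junction_coords(sim.model, j)
            b0, b1 = r.blocks
            # minus strand: the donor sits at the genomic right edge of the skip
            assert b1[0] == donor and b0[1] == acceptor


class TestSimulateCohort:
    def test_null_effect_plants_constant_probability(self):
        res = simulate_cohort(30, SizeEffect(a=-1.0, b=0.0), seed=3, emit_reads=False)
        assert len({j.p_defect for j in res.junctions}) == 1
        # truth defect fractions scatter around logistic(-1) with no size trend
        from scipy.stats import spearmanr

        rho, _ = spearmanr(res.intron_lengths, res.truth_defect_fractions)
        assert abs(rho) < 0.5

    def test_positive_effect_increases_defects_with_length(self):
        res = simulate_cohort(60, SizeEffect(a=-6.0, b=0.55), seed=4, emit_reads=False)
        from scipy.stats import spearmanr

        rho, p = spearmanr(res.intron_lengths, res.truth_defect_fractions)
        assert rho > 0.5 and p < 1e-6

    def test_empty_cohort(self):
        res = simulate_cohort(0, seed=5, emit_reads=False)
        assert res.junctions == [] and res.sims == []

    def test_reads_mode_matches_truth_counts(self):
        res = simulate_cohort(3, SizeEffect(a=-1.0, b=0.0), seed=6, reads_per_junction=100)
        assert len(res.sims) == 3
        for jrec, sim in zip(res.junctions, res.sims):
            assert jrec.truth_counts == sim.truth_counts(2)
            assert sum(jrec.truth_counts.values()) == 100
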