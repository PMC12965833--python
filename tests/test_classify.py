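import numpy as np
import pytest

from gigsplice.alignment import AlignedRead, parse_cigar_string
from gigsplice.classify import (
    Category,
    ClassifierParams,
    JunctionTally,
    backsplice_fraction,
    classify_read,
    resolve_clips,
    tally_junction,
)
from gigsplice.genemodel import Exon, GeneModel
from gigsplice.simulate import JunctionMix, SimConfig, simulate_gene

from _oracles import brute_force_classify


def _read(cigar, pos, seq=None, rid="r"):
    parsed = parse_cigar_string(cigar)
    qlen = sum(n for op, n in parsed if op in "MIS=X")
    return AlignedRead(rid, "chrS", pos, parsed, seq or "A" * qlen)


@pytest.fixture
def gene():
    # exons [500,900) [1400,1800) [2700,3100) on +, donor1=900, acceptor1=1400
    return GeneModel(
        "g", "chrS", "+",
        [Exon(1, 500, 900), Exon(2, 1400, 1800), Exon(3, 2700, 3100)],
    )


class TestClassifyRead:
    def test_canonical_skip_is_spliced(self, gene):
        r = _read("30M500N20M", pos=870)
        assert classify_read(r, gene, 1) is Category.SPLICED

    def test_contiguous_block_across_boundary_is_unspliced(self, gene):
        r = _read("50M", pos=875)  # 25 exon + 25 intron bases
        assert classify_read(r, gene, 1) is Category.UNSPLICED

    def test_long_donor_clip_is_exon_clipped(self, gene):
        r = _read("35M15S", pos=865)
        assert classify_read(r, gene, 1) is Category.EXON_CLIPPED

    def test_short_clip_without_junction_evidence_is_not_informative(self, gene):
        r = _read("42M8S", pos=858)
        assert classify_read(r, gene, 1) is Category.NOT_INFORMATIVE

    def test_skip_to_intronic_acceptor_is_exon_other(self, gene):
        # canonical acceptor 1400; acceptor 500 nt downstream of it
        r = _read("30M1000N20M", pos=870)
        assert classify_read(r, gene, 1) is Category.EXON_OTHER

    def test_known_alt_acceptor_is_excluded(self, gene):
        gene.known_alt_acceptors = frozenset({1900})
        r = _read("30M1000N20M", pos=870)
        assert classify_read(r, gene, 1) is Category.EXCLUDED

    def test_read_ending_at_donor_is_not_informative(self, gene):
        r = _read("40M", pos=860)  # ends exactly at donor, no evidence beyond
        assert classify_read(r, gene, 1) is Category.NOT_INFORMATIVE

    def test_last_exon_raises(self, gene):
        with pytest.raises(IndexError):
            classify_read(_read("40M", 860), gene, 3)

    def test_clip_threshold_boundary_10_vs_11(self, gene):
        # the rule is "clip strictly greater than 10 nt"
        at10 = _read("40M10S", pos=860)
        at11 = _read("40M11S", pos=860)
        assert classify_read(at10, gene, 1) is not Category.EXON_CLIPPED
        assert classify_read(at11, gene, 1) is Category.EXON_CLIPPED

    def test_clip_precedence_over_short_junction_evidence(self, gene):
        # clipped exactly at donor wins over nothing else; short clip falls back
        short = _read("25M500N15M10S", pos=875)  # clip at acceptor side, not donor
        assert classify_read(short, gene, 1) is Category.SPLICED


class TestTally:
    def test_empty_input_gives_zero_tally(self, gene):
        t = tally_junction([], gene, 1)
        assert t.n_total == 0

    def test_all_spliced(self, gene):
        reads = [_read("30M500N20M", pos=870, rid=f"r{i}") for i in range(5)]
        t = tally_junction(reads, gene, 1)
        assert t.n_spliced == t.n_total == 5

    def test_counts_invariant_to_read_order(self, mixed_sim):
        rng = np.random.default_rng(0)
        reads = list(mixed_sim.reads)
        t1 = tally_junction(reads, mixed_sim.model, 4)
        rng.shuffle(reads)
        t2 = tally_junction(reads, mixed_sim.model, 4)
        assert (t1.n_spliced, t1.n_unspliced, t1.n_exon_other, t1.n_exon_clipped) == (
            t2.n_spliced, t2.n_unspliced, t2.n_exon_other, t2.n_exon_clipped
        )

    def test_simulator_fractions_recovered(self, mixed_sim):
        # junction 4 was planted with mix (0.55, 0.25, 0.05, 0.12, 0.03);
        # back-spliced and chimeric truth reads surface as exon-clipped
        reads = [r for r in mixed_sim.reads if mixed_sim.truth[r.read_id].junction_index == 4]
        t = tally_junction(reads, mixed_sim.model, 4)
        n = t.n_total
        assert n == len(reads)
        for got, p in [
            (t.n_spliced, 0.55), (t.n_unspliced, 0.25),
            (t.n_exon_other, 0.05), (t.n_exon_clipped, 0.15),
        ]:
            assert abs(got / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_threshold_monotonicity(self, mixed_sim):
        counts = []
        for mcl in (5, 11, 20, 40):
            t = tally_junction(
                mixed_sim.reads, mixed_sim.model, 4, ClassifierParams(min_clip_len=mcl)
            )
            counts.append(t.n_exon_clipped)
        assert counts == sorted(counts, reverse=True)


class TestOracleEquivalence:
    def test_brute_force_agrees_on_every_simulator_read(self, mixed_sim):
        ref = mixed_sim.reference[mixed_sim.model.chromosome]
        disagree = 0
        for r in mixed_sim.reads:
            j = mixed_sim.truth[r.read_id].junction_index
            ours = classify_read(r, mixed_sim.model, j).value
            oracle = brute_force_classify(r, mixed_sim.model, j, ref)
            if ours != oracle:
                disagree += 1
        assert disagree == 0

    def test_brute_force_agrees_on_minus_strand(self):
        mix = JunctionMix(0.6, 0.2, 0.1, 0.08, 0.02)
        cfg = SimConfig(
            exon_lengths=[400] * 5, intron_lengths=[500, 900, 700, 1100],
            strand="-", mixes=[JunctionMix(), mix, mix, mix],
            reads_per_junction=200, seed=9,
        )
        sim = simulate_gene(cfg)
        ref = sim.reference[cfg.chromosome]
        for r in sim.reads:
            j = sim.truth[r.read_id].junction_index
            assert classify_read(r, sim.model, j).value == brute_force_classify(
                r, sim.model, j, ref
            )


class TestResolveClips:
    def _clipped_at(self, sim, junction):
        out = []
        for r in sim.reads:
            rec = sim.truth[r.read_id]
            if rec.junction_index == junction and rec.category in ("backsplice", "chimera"):
                out.append(r)
        return out

    def test_truth_recovery_perfect_with_unique_prefixes(self, mixed_sim):
        ref = mixed_sim.reference[mixed_sim.model.chromosome]
        for j in (4, 6, 7):
            clipped = self._clipped_at(mixed_sim, j)
            res = resolve_clips(clipped, mixed_sim.model, ref, j)
            truth = {}
            for r in clipped:
                acc = mixed_sim.truth[r.read_id].acceptor_exon
                if acc is not None:
                    truth[acc] = truth.get(acc, 0) + 1
            got = {e.acceptor_exon_index: e.support for e in res.events}
            assert got == truth
            n_chimera = sum(
                1 for r in clipped if mixed_sim.truth[r.read_id].category == "chimera"
            )
            assert res.unassigned == n_chimera
            assert not res.ambiguous and not res.distal_forward

    def test_duplicated_exon_mode_flags_ambiguity_without_false_assignment(self):
        cfg = SimConfig(
            exon_lengths=[400] * 6, intron_lengths=[500, 700, 900, 600, 800],
            mixes=[JunctionMix()] * 4 + [JunctionMix(0.5, 0, 0, 0.5, 0)],
            reads_per_junction=[0, 0, 0, 0, 200],
            backsplice_targets={5: [(2, 1.0)]},
            duplicated_exons=(2, 4, 60),  # exon 4 shares exon 2's first 60 nt
            seed=11,
        )
        sim = simulate_gene(cfg)
        ref = sim.reference[cfg.chromosome]
        clipped = self._clipped_at(sim, 5)
        res = resolve_clips(clipped, sim.model, ref, 5)
        assert res.ambiguous and all(e.candidates == (2, 4) for e in res.ambiguous)
        # nothing assigned to a wrong acceptor: only exon 2 may appear, and only
        # for clips longer than the duplicated prefix (none here: prefix = 60)
        assert not res.events
        assert sum(e.support for e in res.ambiguous) == len(clipped)

    def test_clip_matching_later_exon_reported_as_distal_not_backsplice(self, gene):
        # clip equal to exon 3's 5' prefix at the donor of exon 1
        ref = "".join(
            np.random.default_rng(1).choice(list("ACGT"), 3200)
        )
        clip = ref[2700:2715]
        r = _read("40M15S", pos=860, seq="A" * 40 + clip)
        res = resolve_clips([r], gene, ref, 1)
        assert res.distal_forward == {3: 1} and not res.events

    def test_non_clipped_read_rejected(self, gene):
        with pytest.raises(ValueError, match="not exon-clipped"):
            resolve_clips([_read("40M", 860)], gene, "A" * 3200, 1)


class TestBackspliceFraction:
    def test_arithmetic(self):
        t = JunctionTally("g", 5, n_spliced=600, n_unspliced=120, n_exon_other=37,
                          n_exon_clipped=243)
        assert t.n_total == 1000
        from gigsplice.classify import BackspliceEvent, ClipResolution

        res = ClipResolution(
            events=[BackspliceEvent("g", 5, 2, 90), BackspliceEvent("g", 5, 4, 70)],
            ambiguous=[], distal_forward={}, unassigned=83,
        )
        s = backsplice_fraction(t, res)
        assert s.clipped_fraction == pytest.approx(0.243)
        assert s.assigned_of_clipped == pytest.approx(160 / 243)
        assert s.breakdown == {2: 90, 4: 70}

    def test_zero_clipped(self):
        from gigsplice.classify import ClipResolution

        t = JunctionTally("g", 1, n_spliced=10)
        s = backsplice_fraction(t, ClipResolution([], [], {}, 0))
        assert s.clipped_fraction == 0 and s.assigned_of_clipped == 0

    def test_empty_tally_flagged(self):
        from gigsplice.classify import ClipResolution

        with pytest.raises(ValueError, match="undefined"):
            backsplice_fraction(JunctionTally("g", 1), ClipResolution([], [], {}, 0))
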