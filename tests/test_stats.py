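import math

import numpy as np
import pytest
from scipy import stats as sps

from gigsplice.classify import JunctionTally
from gigsplice.stats import (
    bin_and_test,
    compare_junction,
    compare_junctions,
    defect_frequency,
    size_bin,
    spearman_size_defect,
    splicing_efficiency,
)


def T(s, u, o, c, j=1):
    return JunctionTally("g", j, s, u, o, c)


class TestDefectFrequency:
    @pytest.mark.parametrize(
        "counts,expected",
        [((75, 20, 3, 2), 0.25), ((100, 0, 0, 0), 0.0), ((0, 50, 25, 25), 1.0)],
    )
    def test_value(self, counts, expected):
        assert defect_frequency(T(*counts)).value == pytest.approx(expected)

    def test_empty_tally_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            defect_frequency(T(0, 0, 0, 0))

    def test_complement_of_spliced_fraction(self):
        t = T(63, 21, 9, 7)
        assert defect_frequency(t).value + t.n_spliced / t.n_total == pytest.approx(1.0)

    def test_efficiency_variant_uses_spliced_plus_nascent_only(self):
        t = T(80, 20, 50, 50)
        assert splicing_efficiency(t) == pytest.approx(0.8)


class TestCompareJunction:
    def test_identical_groups_null(self):
        r = compare_junction(T(80, 20, 0, 0), T(80, 20, 0, 0))
        assert abs(r.effect) < 1e-9 and r.p_value > 0.99

    def test_strong_difference_rejected(self):
        # independent oracle: Fisher exact on the same 2x2 table
        r = compare_junction(T(90, 10, 0, 0), T(50, 50, 0, 0))
        _, p_fisher = sps.fisher_exact([[90, 10], [50, 50]])
        assert p_fisher < 1e-6 and r.p_value < 1e-6

    def test_glm_evidence_tracks_chisquare(self):
        # Wald and score tests diverge on the raw p scale for large effects;
        # their implied z statistics must stay close
        r = compare_junction(T(90, 10, 0, 0), T(50, 50, 0, 0))
        chi2, p_chi, _, _ = sps.chi2_contingency([[90, 10], [50, 50]], correction=False)
        z_wald = sps.norm.isf(r.p_value / 2)
        z_score = math.sqrt(chi2)
        assert abs(z_wald - z_score) / z_score < 0.15

    def test_glm_p_matches_chisquare_closely_near_null(self):
        r = compare_junction(T(210, 190, 0, 0), T(195, 205, 0, 0))
        _, p_chi, _, _ = sps.chi2_contingency([[210, 190], [195, 205]], correction=False)
        assert r.p_value == pytest.approx(p_chi, rel=0.10)

    def test_separation_falls_back_to_finite_p(self):
        r = compare_junction(T(100, 0, 0, 0), T(0, 100, 0, 0))
        assert math.isfinite(r.p_value) and r.p_value < 1e-6 and r.method == "fisher"

    def test_antisymmetry(self):
        a, b = T(85, 15, 0, 0), T(60, 30, 5, 5)
        fwd = compare_junction(a, b)
        rev = compare_junction(b, a)
        assert fwd.effect == pytest.approx(-rev.effect)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-6)

    def test_replicates_pooled(self):
        pooled = compare_junction([T(40, 10, 0, 0), T(45, 5, 0, 0)], T(50, 50, 0, 0))
        direct = compare_junction(T(85, 15, 0, 0), T(50, 50, 0, 0))
        assert pooled.p_value == pytest.approx(direct.p_value)

    def test_bh_adjustment_monotone_in_rank(self):
        pairs = [
            (T(90, 10, 0, 0), T(50, 50, 0, 0)),
            (T(80, 20, 0, 0), T(75, 25, 0, 0)),
            (T(70, 30, 0, 0), T(68, 32, 0, 0)),
            (T(90, 10, 0, 0), T(85, 15, 0, 0)),
        ]
        results = compare_junctions(pairs)
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in results)
        ordered = sorted(results, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in ordered]
        assert adj == sorted(adj)
        assert all(q <= 1 for q in adj)


class TestBinAndTest:
    def test_bin_labels(self):
        assert [size_bin(x) for x in (100, 2_700, 60_000)] == [4, 7, 11]

    def test_identical_defect_vectors_give_p_one(self):
        d = [0.1, 0.2, 0.3, 0.15, 0.25, 0.2]
        res = bin_and_test(d, d, [3000] * 6)
        assert all(b.p_value == 1.0 for b in res)

    def test_small_bins_skipped_with_notice(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = bin_and_test([0.1, 0.2, 0.2], [0.2, 0.3, 0.3], [100, 3000, 3100])
        assert [b.bin_label for b in res] == [8]

    def test_planted_shift_detected_in_shifted_bin_only(self):
        rng = np.random.default_rng(7)
        n = 40
        lengths = np.concatenate([
            rng.integers(3000, 8000, n),         # bin 8
            rng.integers(25_000, 59_000, n),     # bin 10
        ])
        base = rng.uniform(0.1, 0.3, 2 * n)
        shifted = base + np.where(np.arange(2 * n) >= n, 0.2, 0.0)
        noise = rng.normal(0, 0.02, 2 * n)
        res = bin_and_test(base, shifted + noise, lengths)
        by_bin = {b.bin_label: b for b in res}
        assert by_bin[10].p_adjusted < 0.05
        assert by_bin[8].p_adjusted > 0.05


class TestSpearman:
    def test_monotone_gives_rho_one(self):
        rho, p = spearman_size_defect([0.1, 0.2, 0.3, 0.4], [100, 1000, 10_000, 100_000])
        assert rho == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_size_defect([0.2, 0.2, 0.2], [100, 1000, 10_000])

    def test_too_few_junctions(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_size_defect([0.1, 0.2], [100, 1000])
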