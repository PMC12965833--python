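"""Differential-splicing statistics.

* per-junction splicing-defect frequency (1 - spliced/all informative reads),
* a binomial GLM (logit link) comparing spliced vs. non-spliced counts
  between two conditions at each junction, Wald test on the group
  coefficient with a Fisher-exact fallback for sparse or separated tables,
* intron-size binning on a natural-log scale with a paired two-sided
  Wilcoxon signed-rank test per bin,
* Spearman rank correlation between intron size and defect frequency.

Benjamini–Hochberg adjustment is applied within each family (all junctions
of one comparison run; all size bins of one binned test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import fdrcorrection

from .classify import JunctionTally

__all__ = [
    "DefectFrequency",
    "JunctionComparison",
    "SizeBinResult",
    "defect_frequency",
    "compare_junction",
    "compare_junctions",
    "bin_and_test",
    "spearman_size_defect",
]


@dataclass(frozen=True)
class DefectFrequency:
    gene_id: str
    exon_index: int
    value: float
    n_total: int


def defect_frequency(tally: JunctionTally) -> DefectFrequency:
    """Splicing-defect frequency: 1 - correctly spliced / all informative reads.

    Counts every informative non-spliced read (unspliced, mis-spliced,
    clipped) as defective.  Undefined (error) on an empty tally.
    """
    if tally.n_total == 0:
        raise ValueError(
            f"gene {tally.gene_id} exon {tally.exon_index}: no informative reads; "
            "defect frequency undefined"
        )
    bad = tally.n_unspliced + tally.n_exon_other + tally.n_exon_clipped
    return DefectFrequency(
        gene_id=tally.gene_id,
        exon_index=tally.exon_index,
        value=bad / tally.n_total,
        n_total=tally.n_total,
    )


def splicing_efficiency(tally: JunctionTally) -> float:
    """Alternative statistic: spliced / (spliced + unspliced) reads only.

    Restricts the denominator to reads with an unambiguous spliced-or-nascent
    call, ignoring clipped and mis-spliced reads.  Exposed as an optional
    column; the defect frequency above is the pipeline's primary statistic.
    """
    denom = tally.n_spliced + tally.n_unspliced
    if denom == 0:
        raise ValueError("no spliced or unspliced reads; efficiency undefined")
    return tally.n_spliced / denom


@dataclass
class JunctionComparison:
    gene_id: str
    exon_index: int
    spliced_a: int
    failed_a: int
    spliced_b: int
    failed_b: int
    effect: float          # log-odds(spliced in B) - log-odds(spliced in A)
    p_value: float
    method: str            # "glm-wald" or "fisher"
    p_adjusted: float = float("nan")


def _pool(tallies: Sequence[JunctionTally]) -> tuple[int, int]:
    s = sum(t.n_spliced for t in tallies)
    f = sum(t.n_unspliced + t.n_exon_other + t.n_exon_clipped for t in tallies)
    return s, f


def compare_junction(
    tallies_a: Sequence[JunctionTally] | JunctionTally,
    tallies_b: Sequence[JunctionTally] | JunctionTally,
) -> JunctionComparison:
    """Binomial GLM of spliced vs. non-spliced counts on a group indicator.

    Replicates are pooled per group (an overdispersion warning is emitted if
    replicate spliced fractions disagree strongly).  Inference is a Wald test
    on the group log-odds coefficient; when any pooled cell is < 5 or the
    table is separated, a two-sided Fisher exact test is used instead and the
    effect is a Haldane-corrected log odds ratio.
    """
    if isinstance(tallies_a, JunctionTally):
        tallies_a = [tallies_a]
    if isinstance(tallies_b, JunctionTally):
        tallies_b = [tallies_b]
    if not tallies_a or not tallies_b:
        raise ValueError("need at least one replicate tally per group")
    sa, fa = _pool(tallies_a)
    sb, fb = _pool(tallies_b)
    if sa + fa == 0 or sb + fb == 0:
        raise ValueError("a group has no informative reads at this junction")
    _check_overdispersion(tallies_a, "A")
    _check_overdispersion(tallies_b, "B")

    gene = tallies_a[0].gene_id
    exon = tallies_a[0].exon_index
    table = np.array([[sa, fa], [sb, fb]], dtype=float)

    if (table < 5).any():
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        effect = _haldane_log_or(sb, fb, sa, fa)
        method = "fisher"
    else:
        endog = table  # rows: (successes, failures) per group
        exog = sm.add_constant(np.array([0.0, 1.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        effect = float(fit.params[1])
        p = float(fit.pvalues[1])
        method = "glm-wald"
        if not math.isfinite(p) or abs(effect) > 30:  # separation guard
            _, p = sps.fisher_exact(table, alternative="two-sided")
            effect = _haldane_log_or(sb, fb, sa, fa)
            method = "fisher"
    return JunctionComparison(
        gene_id=gene, exon_index=exon,
        spliced_a=sa, failed_a=fa, spliced_b=sb, failed_b=fb,
        effect=effect, p_value=p, method=method,
    )


def _haldane_log_or(sb: int, fb: int, sa: int, fa: int) -> float:
    return math.log(((sb + 0.5) / (fb + 0.5)) / ((sa + 0.5) / (fa + 0.5)))


def _check_overdispersion(tallies: Sequence[JunctionTally], label: str) -> None:
    if len(tallies) < 2:
        return
    fracs, ns = [], []
    for t in tallies:
        if t.n_total:
            fracs.append(t.n_spliced / t.n_total)
            ns.append(t.n_total)
    if len(fracs) < 2:
        return
    p = float(np.average(fracs, weights=ns))
    if p in (0.0, 1.0):
        return
    chi2 = sum(n * (f - p) ** 2 / (p * (1 - p)) for f, n in zip(fracs, ns))
    dof = len(fracs) - 1
    if chi2 / dof > 4:
        warnings.warn(
            f"group {label}: replicate spliced fractions are overdispersed "
            f"(X2/df = {chi2 / dof:.1f}); pooled GLM p-values may be anticonservative"
        )


def compare_junctions(
    pairs: Sequence[tuple[Sequence[JunctionTally] | JunctionTally,
                          Sequence[JunctionTally] | JunctionTally]],
) -> list[JunctionComparison]:
    """Run :func:`compare_junction` over many junctions; BH-adjust across them."""
    results = [compare_junction(a, b) for a, b in pairs]
    if results:
        _, p_adj = fdrcorrection([r.p_value for r in results], alpha=0.05)
        for r, q in zip(results, p_adj):
            r.p_adjusted = float(q)
    return results


@dataclass
class SizeBinResult:
    bin_label: int                 # floor of natural log of intron length
    n_junctions: int
    mean_defect_a: float
    mean_defect_b: float
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")


def size_bin(intron_length: float) -> int:
    """Bin label: integer floor of the natural log of the intron length."""
    if intron_length <= 0:
        raise ValueError("intron length must be positive")
    return int(math.floor(math.log(intron_length)))


def bin_and_test(
    defects_a: Sequence[float],
    defects_b: Sequence[float],
    intron_lengths: Sequence[float],
    min_pairs: int = 2,
) -> list[SizeBinResult]:
    """Paired Wilcoxon signed-rank per intron-size bin, BH across bins.

    The same junctions must be measured in both conditions (paired by
    position).  Bins are ``floor(ln length)``; bins with fewer than
    ``min_pairs`` junctions are skipped with a warning.  Zero differences are
    dropped (standard signed-rank handling); the exact null distribution is
    used for n < 25, the normal approximation otherwise.
    """
    a = np.asarray(defects_a, dtype=float)
    b = np.asarray(defects_b, dtype=float)
    L = np.asarray(intron_lengths, dtype=float)
    if not (len(a) == len(b) == len(L)):
        raise ValueError("defect vectors and intron lengths must be paired and equal length")
    bins = np.array([size_bin(x) for x in L])
    results: list[SizeBinResult] = []
    for lab in sorted(set(bins.tolist())):
        idx = bins == lab
        if idx.sum() < min_pairs:
            warnings.warn(f"size bin {lab}: only {int(idx.sum())} junction(s); skipped")
            continue
        xa, xb = a[idx], b[idx]
        diffs = xb - xa
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            n_nonzero = int(np.count_nonzero(diffs))
            method = "exact" if n_nonzero < 25 else "approx"
            stat, p = sps.wilcoxon(
                xa, xb, zero_method="wilcox", alternative="two-sided", method=method
            )
        results.append(
            SizeBinResult(
                bin_label=int(lab),
                n_junctions=int(idx.sum()),
                mean_defect_a=float(xa.mean()),
                mean_defect_b=float(xb.mean()),
                statistic=float(stat),
                p_value=float(p),
            )
        )
    if results:
        _, p_adj = fdrcorrection([r.p_value for r in results], alpha=0.05)
        for r, q in zip(results, p_adj):
            r.p_adjusted = float(q)
    return results


def spearman_size_defect(
    defects: Sequence[float], intron_lengths: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of intron size vs. defect frequency."""
    d = np.asarray(defects, dtype=float)
    L = np.asarray(intron_lengths, dtype=float)
    if len(d) != len(L):
        raise ValueError("defects and intron lengths must be paired")
    if len(d) < 3:
        raise ValueError("need at least 3 junctions for a rank correlation")
    if np.all(d == d[0]) or np.all(L == L[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(L, d)
    return float(rho), float(p)
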