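"""Independent reference implementations used only to cross-check results.

These deliberately take a different computational route from the package:
the classifier oracle works from a per-query-base reference mapping verified
against the reference sequence, and the alignment oracle is a quadratic-space
Gotoh dynamic program.
"""

from __future__ import annotations

import numpy as np

from gigsplice.alignment import AlignedRead
from gigsplice.genemodel import GeneModel, junction_coords


def query_to_reference_map(read: AlignedRead) -> list[int | None]:
    """Map each query index to its reference position (None for clips/inserts)."""
    out: list[int | None] = []
    ref = read.pos
    for op, n in read.cigar:
        if op in "M=X":
            out.extend(range(ref, ref + n))
            ref += n
        elif op in "DN":
            ref += n
        elif op in "IS":
            out.extend([None] * n)
    return out


def brute_force_classify(
    read: AlignedRead,
    model: GeneModel,
    exon_index: int,
    reference: str,
    min_clip_len: int = 11,
    min_overhang: int = 1,
) -> str:
    """Re-derive the category from first principles on a gap-free fixture.

    Verifies every aligned base against the reference (zero-mismatch regime),
    then inspects which reference positions flank the donor boundary in the
    query, instead of walking CIGAR blocks.
    """
    qmap = query_to_reference_map(read)
    for q, r in enumerate(qmap):
        if r is not None:
            assert reference[r] == read.sequence[q], "aligned base disagrees with reference"

    donor, acceptor = junction_coords(model, exon_index)
    plus = model.strand == "+"
    # reference position of the last transcribed exon base before the boundary
    last_exon_ref = donor - 1 if plus else donor

    positions = [i for i, r in enumerate(qmap) if r == last_exon_ref]
    if not positions:
        return "not_informative"
    q = positions[0]
    nxt_q = q + 1 if plus else q - 1

    # clipped at the boundary: everything beyond the donor-side base is unaligned
    if plus:
        tail = qmap[q + 1 :]
    else:
        tail = qmap[: q][::-1]
    if tail and all(r is None for r in tail):
        if len(tail) >= min_clip_len:
            return "exon_clipped"
        return "not_informative"

    if not 0 <= nxt_q < len(qmap) or qmap[nxt_q] is None:
        return "not_informative"
    nxt_ref = qmap[nxt_q]
    canonical_next = acceptor if plus else acceptor - 1
    intron_next = donor if plus else donor - 1
    if nxt_ref == canonical_next:
        return "spliced"
    if nxt_ref == intron_next:
        # needs min_overhang bases of contiguous intronic evidence
        run = 0
        step = 1 if plus else -1
        expect = nxt_ref
        qq = nxt_q
        while 0 <= qq < len(qmap) and qmap[qq] == expect:
            run += 1
            qq += step
            expect += step if plus else -step
        return "unspliced" if run >= min_overhang else "not_informative"
    if (plus and nxt_ref in model.known_alt_acceptors) or (
        not plus and nxt_ref + 1 in model.known_alt_acceptors
    ):
        return "excluded"
    return "exon_other"


def gotoh_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Affine-gap global alignment score by an explicit Gotoh recursion.

    First gap position costs ``gap_open``, each subsequent ``gap_extend``;
    end gaps are penalized like internal ones.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))
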