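"""Classification of reads overlapping exon 3' ends, and clip resolution.

Every informative read at a junction falls in exactly one category:

* **Exon-clipped** — the alignment ends exactly at the donor boundary in a
  soft clip strictly longer than 10 nt (default): the bases following the exon
  could not be placed linearly.
* **Spliced** — a skip joins the donor to the annotated downstream acceptor.
* **Unspliced** — a contiguous aligned block crosses the exon–intron boundary
  (nascent RNA).
* **Exon-other** — a skip joins the donor to any other position.  Acceptors
  belonging to known alternative isoforms or overlapping genes are excluded
  from counting altogether.

Clip-first precedence: a long donor-side clip is the junction evidence itself,
so it wins over any other signal on the same read.  Short clips (1–10 nt) are
treated as aligner noise: such reads are classified by their remaining
evidence or dropped as not informative.

``resolve_clips`` then compares each clip against the 5' prefix of every other
exon of the gene; a unique match to an *earlier* exon is the linear-alignment
signature of back-splicing (circular RNA formation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import AlignedRead, observed_junctions
from .genemodel import GeneModel, junction_coords
from .simulate import exon_five_prime_comparator

__all__ = [
    "Category",
    "ClassifierParams",
    "JunctionTally",
    "BackspliceEvent",
    "ClipResolution",
    "BackspliceSummary",
    "classify_read",
    "tally_junction",
    "resolve_clips",
    "backsplice_fraction",
]


class Category(enum.Enum):
    SPLICED = "spliced"
    UNSPLICED = "unspliced"
    EXON_OTHER = "exon_other"
    EXON_CLIPPED = "exon_clipped"
    EXCLUDED = "excluded"           # known alternative acceptor
    NOT_INFORMATIVE = "not_informative"


INFORMATIVE = (Category.SPLICED, Category.UNSPLICED, Category.EXON_OTHER, Category.EXON_CLIPPED)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the junction classifier.

    ``min_clip_len=11`` implements the "clip strictly greater than 10 nt"
    rule; ``min_overhang`` is the evidence required beyond the donor;
    ``clip_match_len`` caps how many clip bases are compared to exon prefixes
    (None = full clip); ``max_clip_mismatches=0`` demands identity.
    """

    min_clip_len: int = 11
    min_overhang: int = 1
    clip_match_len: int | None = None
    max_clip_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")


@dataclass
class JunctionTally:
    gene_id: str
    exon_index: int
    n_spliced: int = 0
    n_unspliced: int = 0
    n_exon_other: int = 0
    n_exon_clipped: int = 0

    @property
    def n_total(self) -> int:
        return self.n_spliced + self.n_unspliced + self.n_exon_other + self.n_exon_clipped

    def add(self, category: Category) -> None:
        if category is Category.SPLICED:
            self.n_spliced += 1
        elif category is Category.UNSPLICED:
            self.n_unspliced += 1
        elif category is Category.EXON_OTHER:
            self.n_exon_other += 1
        elif category is Category.EXON_CLIPPED:
            self.n_exon_clipped += 1


@dataclass
class BackspliceEvent:
    gene_id: str
    donor_exon_index: int
    acceptor_exon_index: int
    support: int
    ambiguous: bool = False
    candidates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.ambiguous and self.acceptor_exon_index >= self.donor_exon_index:
            raise ValueError("back-splice acceptor must be an earlier exon")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class ClipResolution:
    """Outcome of matching donor-side clips against exon 5' prefixes."""

    events: list[BackspliceEvent]          # unambiguous earlier-exon matches
    ambiguous: list[BackspliceEvent]       # tied matches, flagged, not assigned
    distal_forward: dict[int, int]         # later-exon matches: exon -> support
    unassigned: int                        # clips matching nothing

    @property
    def assigned_support(self) -> int:
        return sum(e.support for e in self.events)


def _donor_side_clip(read: AlignedRead, donor: int, plus_strand: bool) -> str | None:
    """The soft clip sitting exactly at the donor boundary, else None."""
    blocks = read.blocks
    if plus_strand:
        if blocks and blocks[-1][1] == donor and read.right_clip:
            return read.right_clip
    else:
        if blocks and blocks[0][0] == donor and read.left_clip:
            return read.left_clip
    return None


def classify_read(
    read: AlignedRead,
    model: GeneModel,
    exon_index: int,
    params: ClassifierParams = ClassifierParams(),
) -> Category:
    """Assign one category to a read at the junction following ``exon_index``.

    Precedence: donor-boundary clip of >= ``min_clip_len`` -> EXON_CLIPPED;
    skip donor->canonical acceptor -> SPLICED; contiguous block crossing the
    boundary -> UNSPLICED; skip donor->elsewhere -> EXON_OTHER unless the
    acceptor is a known alternative-isoform acceptor (EXCLUDED).  Anything
    else is NOT_INFORMATIVE.
    """
    donor, acceptor = junction_coords(model, exon_index)
    plus = model.strand == "+"

    clip = _donor_side_clip(read, donor, plus)
    if clip is not None and len(clip) >= params.min_clip_len:
        return Category.EXON_CLIPPED

    for obs in observed_junctions(read):
        if plus and obs.donor_pos == donor:
            if obs.acceptor_pos == acceptor:
                return Category.SPLICED
            if obs.acceptor_pos in model.known_alt_acceptors:
                return Category.EXCLUDED
            return Category.EXON_OTHER
        if not plus and obs.acceptor_pos == donor:
            # minus strand: the donor sits at the genomic *right* edge of the skip
            if obs.donor_pos == acceptor:
                return Category.SPLICED
            if obs.donor_pos in model.known_alt_acceptors:
                return Category.EXCLUDED
            return Category.EXON_OTHER

    for b0, b1 in read.blocks:
        if b0 < donor < b1:
            beyond = (b1 - donor) if plus else (donor - b0)
            exon_side = (donor - b0) if plus else (b1 - donor)
            if beyond >= params.min_overhang and exon_side >= 1:
                return Category.UNSPLICED

    return Category.NOT_INFORMATIVE


def tally_junction(
    reads: Iterable[AlignedRead],
    model: GeneModel,
    exon_index: int,
    params: ClassifierParams = ClassifierParams(),
) -> JunctionTally:
    """Count informative reads per category at one exon 3' end.

    EXCLUDED and NOT_INFORMATIVE reads do not enter ``n_total``.
    """
    tally = JunctionTally(gene_id=model.gene_id, exon_index=exon_index)
    for read in reads:
        tally.add(classify_read(read, model, exon_index, params))
    return tally


def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def resolve_clips(
    clipped_reads: Sequence[AlignedRead],
    model: GeneModel,
    reference: str | dict[str, str],
    exon_index: int,
    params: ClassifierParams = ClassifierParams(),
) -> ClipResolution:
    """Match donor-side clips to exon 5' prefixes; report back-splice events.

    Each clip is compared (transcription orientation, donor-adjacent end
    first) to the 5' prefix of every other exon of the gene.  A unique best
    match with <= ``max_clip_mismatches`` to an earlier exon becomes a
    :class:`BackspliceEvent`; a unique match to a later exon is reported as a
    distal-forward-splice candidate, never as back-splicing; ties are flagged
    ambiguous and counted without assignment; non-matching clips are
    unassigned.
    """
    if isinstance(reference, dict):
        if model.chromosome not in reference:
            raise KeyError(f"reference sequence for {model.chromosome} missing")
        reference = reference[model.chromosome]
    donor, _ = junction_coords(model, exon_index)
    plus = model.strand == "+"

    support: dict[int, int] = {}
    ambiguous_support: dict[tuple[int, ...], int] = {}
    distal: dict[int, int] = {}
    unassigned = 0

    for read in clipped_reads:
        clip = _donor_side_clip(read, donor, plus)
        if clip is None or len(clip) < params.min_clip_len:
            raise ValueError(
                f"read {read.read_id} is not exon-clipped at the donor of exon {exon_index}"
            )
        c = len(clip)
        if params.clip_match_len is not None:
            c = min(c, params.clip_match_len)
        probe = clip[:c] if plus else clip[-c:]

        best: list[int] = []
        best_mm = params.max_clip_mismatches + 1
        for b in range(1, model.n_exons + 1):
            if b == exon_index:
                continue
            k = min(c, model.exon_by_index(b).length)
            cmpr = exon_five_prime_comparator(model, reference, b, k)
            sub = probe[:k] if plus else probe[-k:]
            mm = _count_mismatches(sub, cmpr)
            if mm < best_mm:
                best, best_mm = [b], mm
            elif mm == best_mm:
                best.append(b)
        if best_mm > params.max_clip_mismatches or not best:
            unassigned += 1
        elif len(best) > 1:
            key = tuple(sorted(best))
            ambiguous_support[key] = ambiguous_support.get(key, 0) + 1
        elif best[0] < exon_index:
            support[best[0]] = support.get(best[0], 0) + 1
        else:
            distal[best[0]] = distal.get(best[0], 0) + 1

    events = [
        BackspliceEvent(model.gene_id, exon_index, acc, n)
        for acc, n in sorted(support.items())
    ]
    ambiguous = [
        BackspliceEvent(
            model.gene_id, exon_index, cands[0], n, ambiguous=True, candidates=cands
        )
        for cands, n in sorted(ambiguous_support.items())
    ]
    return ClipResolution(
        events=events, ambiguous=ambiguous, distal_forward=distal, unassigned=unassigned
    )


@dataclass
class BackspliceSummary:
    clipped_fraction: float        # exon-clipped reads / all informative reads
    assigned_fraction: float       # assigned back-splice support / all informative reads
    assigned_of_clipped: float     # assigned support / exon-clipped reads
    breakdown: dict[int, int]      # acceptor exon -> support


def backsplice_fraction(tally: JunctionTally, resolution: ClipResolution) -> BackspliceSummary:
    """Fraction of donor-overlapping reads that are back-spliced, per acceptor."""
    if tally.n_total == 0:
        raise ValueError(
            f"gene {tally.gene_id} exon {tally.exon_index}: no informative reads; "
            "back-splice fraction undefined"
        )
    assigned = resolution.assigned_support
    return BackspliceSummary(
        clipped_fraction=tally.n_exon_clipped / tally.n_total,
        assigned_fraction=assigned / tally.n_total,
        assigned_of_clipped=(assigned / tally.n_exon_clipped) if tally.n_exon_clipped else 0.0,
        breakdown={e.acceptor_exon_index: e.support for e in resolution.events},
    )
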