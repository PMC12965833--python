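"""Spliced-alignment model and SAM I/O.

:class:`AlignedRead` is the classification substrate: a linear alignment with
its CIGAR decomposed into gapless aligned blocks (split at skips), plus the
soft-clipped tails the aligner could not place.  Skips (``N``) encode observed
splice junctions; soft clips at a donor boundary are the evidence class for
back-splicing.  SAM records are read and written through pysam.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pysam

__all__ = [
    "AlignedRead",
    "SpliceJunctionObs",
    "read_sam",
    "write_sam",
    "observed_junctions",
    "parse_cigar_string",
]

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_CODE = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 6: "P", 7: "=", 8: "X"}
_CODE_CIGAR = {v: k for k, v in _CIGAR_CODE.items()}


def parse_cigar_string(cigar: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string like ``50M1000N50M`` into (op, length) pairs."""
    import re

    if not cigar or not re.fullmatch(r"(?:\d+[MIDNSHP=X])+", cigar):
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return tuple((m.group(2), int(m.group(1))) for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar))


@dataclass(frozen=True)
class SpliceJunctionObs:
    """One observed skip: genomic end of the upstream block, start of the next."""

    donor_pos: int
    acceptor_pos: int

    def __post_init__(self) -> None:
        if self.acceptor_pos <= self.donor_pos:
            raise ValueError("skip acceptor must lie beyond the donor genomically")


@dataclass
class AlignedRead:
    """A linear alignment with soft-clip information.

    ``cigar`` is a list of ``(op, length)`` with ops from ``M I D N S = X``.
    Hard clips are rejected: clip *sequence* is required downstream for
    back-splice matching.  ``blocks``, ``left_clip`` and ``right_clip`` are
    derived lazily from the CIGAR and the stored sequence.
    """

    read_id: str
    chromosome: str
    pos: int  # leftmost aligned position, 0-based
    cigar: tuple[tuple[str, int], ...]
    sequence: str
    mapq: int = 60
    flag: int = 0

    def __post_init__(self) -> None:
        self.cigar = tuple((op, int(n)) for op, n in self.cigar)
        for op, n in self.cigar:
            if op == "H":
                raise ValueError(
                    f"read {self.read_id}: hard clips unsupported (clip sequence "
                    "is required for back-splice matching; re-align with soft clipping)"
                )
            if op not in "MIDNS=X":
                raise ValueError(f"read {self.read_id}: unknown CIGAR op {op!r}")
            if n <= 0:
                raise ValueError(f"read {self.read_id}: non-positive CIGAR length {n}{op}")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def blocks(self) -> list[tuple[int, int]]:
        """Gapless aligned genomic intervals, split at skip (N) ops only."""
        out: list[tuple[int, int]] = []
        ref = self.pos
        start: int | None = None
        for op, n in self.cigar:
            if op in "M=XD":
                if start is None:
                    start = ref
                ref += n
            elif op == "N":
                if start is not None:
                    out.append((start, ref))
                    start = None
                ref += n
            # I and S consume no reference
        if start is not None:
            out.append((start, ref))
        return out

    @property
    def left_clip(self) -> str:
        if self.cigar and self.cigar[0][0] == "S":
            return self.sequence[: self.cigar[0][1]]
        return ""

    @property
    def right_clip(self) -> str:
        if self.cigar and self.cigar[-1][0] == "S":
            return self.sequence[len(self.sequence) - self.cigar[-1][1]:]
        return ""

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def observed_junctions(read: AlignedRead) -> list[SpliceJunctionObs]:
    """One observation per skip op, at the flanking block boundaries."""
    obs = []
    blocks = read.blocks
    ref = read.pos
    bi = 0
    for op, n in read.cigar:
        if op in "M=XD":
            ref += n
        elif op == "N":
            obs.append(SpliceJunctionObs(donor_pos=ref, acceptor_pos=ref + n))
            ref += n
    return obs


def read_sam(
    path: str | os.PathLike,
    region: tuple[str, int, int] | None = None,
    min_mapq: int = 0,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM file.

    Secondary (0x100) and supplementary (0x800) records and unmapped reads are
    skipped; ``region`` filters by overlap of the reference span (streaming —
    no index needed).  Malformed CIGARs raise with the record number.
    """
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh, start=1):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"{path}: record {i} ({rec.query_name}): missing CIGAR")
            try:
                cigar = tuple((_CIGAR_CODE[code], n) for code, n in rec.cigartuples)
                read = AlignedRead(
                    read_id=rec.query_name,
                    chromosome=rec.reference_name,
                    pos=rec.reference_start,
                    cigar=cigar,
                    sequence=rec.query_sequence or "",
                    mapq=rec.mapping_quality,
                    flag=rec.flag,
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: record {i}: {exc}") from exc
            if region is not None:
                chrom, lo, hi = region
                if read.chromosome != chrom or read.reference_end <= lo or read.pos >= hi:
                    continue
            yield read


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | os.PathLike,
    references: dict[str, int],
) -> None:
    """Write reads as SAM with @SQ headers from ``references`` (name -> length)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = r.flag
            seg.reference_id = header.get_tid(r.chromosome)
            seg.reference_start = r.pos
            seg.mapping_quality = r.mapq
            seg.cigartuples = [(_CODE_CIGAR[op], n) for op, n in r.cigar]
            seg.query_sequence = r.sequence
            fh.write(seg)
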