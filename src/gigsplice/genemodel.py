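"""Gene models for splice-junction analysis.

A :class:`GeneModel` holds the ordered exons of one transcript and derives the
intron coordinate system every downstream operation uses: junction donor /
acceptor positions, intron sizes, and assembly-gap annotations.

Coordinates are 0-based half-open internally.  GTF input/output converts
to/from the 1-based inclusive convention at the file boundary.  Exons are kept
in *transcription* order, so for minus-strand genes exon 1 is the exon with the
highest genomic coordinate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "Exon",
    "Intron",
    "GeneModel",
    "read_gtf",
    "write_gtf",
    "intron_sizes",
    "junction_coords",
    "write_junction_bed",
    "write_intron_table",
]


@dataclass(frozen=True)
class Exon:
    """One exon; ``index`` is the 1-based ordinal in transcription order."""

    index: int
    start: int  # genomic, 0-based
    end: int    # genomic, half-open

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.index}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    """Intron ``index`` lies between exon ``index`` and exon ``index+1``.

    ``length`` is assembled sequence only; ``has_gap`` marks an assembly gap of
    unknown extra length (metadata, never added to ``length``).
    """

    index: int
    length: int
    has_gap: bool = False

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"intron {self.index}: negative length {self.length}")


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: list[Exon]
    gap_introns: frozenset[int] = frozenset()
    known_alt_acceptors: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for i, ex in enumerate(self.exons, start=1):
            if ex.index != i:
                raise ValueError(
                    f"gene {self.gene_id}: exon indices must be 1..n in "
                    f"transcription order (got {ex.index} at position {i})"
                )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"gene {self.gene_id}: exons {a.index} and {b.index} overlap"
                )
        # Transcription order: ascending genomic for +, descending for -.
        coords = [e.start for e in self.exons]
        ordered = coords == sorted(coords) if self.strand == "+" else coords == sorted(coords, reverse=True)
        if not ordered:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order for strand {self.strand}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[Intron]:
        out = []
        for i in range(1, self.n_exons):
            up, down = self.exons[i - 1], self.exons[i]
            length = down.start - up.end if self.strand == "+" else up.start - down.end
            out.append(Intron(index=i, length=length, has_gap=i in self.gap_introns))
        return out

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript, 0-based half-open."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def exon_by_index(self, index: int) -> Exon:
        if not 1 <= index <= self.n_exons:
            raise IndexError(f"gene {self.gene_id}: no exon {index} (1..{self.n_exons})")
        return self.exons[index - 1]

    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)


def junction_coords(model: GeneModel, exon_index: int) -> tuple[int, int]:
    """Donor/acceptor genomic positions of the junction after ``exon_index``.

    The donor is the transcription-orientation 3' boundary of exon
    ``exon_index``; the acceptor is the 5' boundary of exon ``exon_index + 1``.
    Positions are genomic 0-based boundaries (for + genes the donor equals the
    exon's half-open ``end``; for - genes it equals the exon's ``start``).
    """
    if not 1 <= exon_index < model.n_exons:
        raise IndexError(
            f"gene {model.gene_id}: exon {exon_index} has no downstream junction "
            f"(valid 1..{model.n_exons - 1})"
        )
    donor_exon = model.exon_by_index(exon_index)
    acceptor_exon = model.exon_by_index(exon_index + 1)
    if model.strand == "+":
        return donor_exon.end, acceptor_exon.start
    return donor_exon.start, acceptor_exon.end


def intron_sizes(model: GeneModel) -> list[tuple[int, int, bool]]:
    """(index, assembled length, has_gap) per intron; [] for single-exon genes.

    Lengths are assembled sequence only — assembly gaps are flagged, never
    added, so size statistics use the known length of each intron.
    """
    return [(i.index, i.length, i.has_gap) for i in model.introns]


def _parse_gtf_db(path: str) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def read_gtf(path: str | os.PathLike, transcript_ids: Iterable[str] | None = None) -> list[GeneModel]:
    """Parse GTF exon records into one :class:`GeneModel` per transcript.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are sorted into transcription order (strand-aware).  Raises if a
    requested transcript has no exon features or if exons overlap.
    """
    db = _parse_gtf_db(os.fspath(path))
    by_tx: dict[str, list[gffutils.Feature]] = {}
    for feat in db.features_of_type("exon"):
        tx = feat.attributes.get("transcript_id", [None])[0]
        if tx is None:
            raise ValueError(f"{path}: exon feature without transcript_id")
        by_tx.setdefault(tx, []).append(feat)

    wanted = list(transcript_ids) if transcript_ids is not None else sorted(by_tx)
    missing = [t for t in wanted if t not in by_tx]
    if missing:
        raise ValueError(f"{path}: no exon features for transcript(s) {', '.join(missing)}")

    models = []
    for tx in wanted:
        feats = by_tx[tx]
        strand = feats[0].strand
        chrom = feats[0].seqid
        gene = feats[0].attributes.get("gene_id", [tx])[0]
        if any(f.strand != strand or f.seqid != chrom for f in feats):
            raise ValueError(f"{path}: transcript {tx} mixes strands or chromosomes")
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        exons = [
            Exon(index=i, start=f.start - 1, end=f.end)
            for i, f in enumerate(feats, start=1)
        ]
        models.append(GeneModel(gene_id=gene, chromosome=chrom, strand=strand, exons=exons))
    return models


def write_gtf(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write exon records (1-based inclusive) for each model."""
    with open(path, "w") as fh:
        for m in models:
            for ex in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}"; exon_number "{ex.index}";'
                fh.write(
                    f"{m.chromosome}\tgigsplice\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def write_junction_bed(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """BED (0-based half-open) of donor->acceptor junction intervals."""
    with open(path, "w") as fh:
        for m in models:
            for i in range(1, m.n_exons):
                donor, acceptor = junction_coords(m, i)
                lo, hi = min(donor, acceptor), max(donor, acceptor)
                fh.write(f"{m.chromosome}\t{lo}\t{hi}\t{m.gene_id}_junction{i}\t0\t{m.strand}\n")


def write_intron_table(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tintron_index\tlength\thas_gap\n")
        for m in models:
            for idx, length, gap in intron_sizes(m):
                fh.write(f"{m.gene_id}\t{idx}\t{length}\t{int(gap)}\n")
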