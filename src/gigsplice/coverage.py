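"""Read-depth profiles along the coding sequence and attenuation ratios.

Depth is accumulated from aligned blocks only (skips and clips contribute
nothing), restricted to exonic positions and laid out in transcription order,
so the x-axis is the position along the coding sequence with introns
collapsed.  Profiles are normalized by the sample's total aligned bases (a
library-size proxy, making the profile invariant to sequencing depth) and
then scaled so the first exon's mean depth is 1 for cross-sample display.

The attenuation ratio at a junction is the mean normalized depth over
downstream exons divided by the mean over upstream exons; an optional trim
excludes a read-length-sized window around the junction and the transcript
ends, where coverage ramps caused by finite read length would otherwise bias
the means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment import AlignedRead
from .genemodel import GeneModel

__all__ = ["CoverageProfile", "AttenuationCall", "coverage", "attenuation_ratio"]


@dataclass
class CoverageProfile:
    gene_id: str
    depth: np.ndarray               # per exonic position, transcription order
    exon_lengths: list[int]
    normalization: float            # total aligned bases used for normalization
    scale: float                    # first-exon mean divisor applied after normalization

    @property
    def exon_offsets(self) -> list[int]:
        out, acc = [], 0
        for n in self.exon_lengths:
            out.append(acc)
            acc += n
        return out

    def exon_mean(self, exon_index: int) -> float:
        off = self.exon_offsets[exon_index - 1]
        return float(self.depth[off : off + self.exon_lengths[exon_index - 1]].mean())


@dataclass(frozen=True)
class AttenuationCall:
    junction_index: int
    upstream_mean: float
    downstream_mean: float

    @property
    def ratio(self) -> float:
        return self.downstream_mean / self.upstream_mean


def coverage(reads: Iterable[AlignedRead], model: GeneModel) -> CoverageProfile:
    """Per-base normalized depth over exonic positions in transcription order."""
    lo, hi = model.span
    genomic = np.zeros(hi - lo, dtype=np.float64)
    total_aligned = 0
    any_overlap = False
    for read in reads:
        if read.chromosome != model.chromosome:
            continue
        for b0, b1 in read.blocks:
            total_aligned += b1 - b0
            s, e = max(b0, lo), min(b1, hi)
            if s < e:
                genomic[s - lo : e - lo] += 1
                any_overlap = True

    parts = []
    for ex in model.exons:
        seg = genomic[ex.start - lo : ex.end - lo]
        if model.strand == "-":
            seg = seg[::-1]
        parts.append(seg)
    depth = np.concatenate(parts)

    if not any_overlap:
        warnings.warn(f"gene {model.gene_id}: no reads overlap; zero coverage profile")
        return CoverageProfile(model.gene_id, depth, [e.length for e in model.exons],
                               normalization=max(total_aligned, 1), scale=1.0)

    depth = depth / total_aligned
    first_len = model.exons[0].length
    scale = float(depth[:first_len].mean())
    if scale > 0:
        depth = depth / scale
    else:
        warnings.warn(f"gene {model.gene_id}: first exon has zero depth; profile left unscaled")
        scale = 1.0
    return CoverageProfile(
        gene_id=model.gene_id,
        depth=depth,
        exon_lengths=[e.length for e in model.exons],
        normalization=total_aligned,
        scale=scale,
    )


def attenuation_ratio(
    profile: CoverageProfile, junction_index: int, trim: int = 0
) -> AttenuationCall:
    """Mean depth over exons downstream of a junction relative to upstream.

    ``trim`` positions (coding-sequence coordinates) are excluded adjacent to
    the junction boundary and at both transcript ends; use roughly one read
    length to remove edge ramps.
    """
    n_exons = len(profile.exon_lengths)
    if not 1 <= junction_index < n_exons:
        raise IndexError(f"junction {junction_index} out of range (1..{n_exons - 1})")
    boundary = sum(profile.exon_lengths[:junction_index])
    total = len(profile.depth)
    up = profile.depth[min(trim, boundary) : max(boundary - trim, 0)]
    down = profile.depth[boundary + trim : max(total - trim, boundary + trim)]
    if up.size == 0 or down.size == 0:
        raise ValueError("trim leaves no positions on one side of the junction")
    up_mean = float(up.mean())
    if up_mean == 0:
        raise ValueError(
            f"junction {junction_index}: upstream mean depth is zero; ratio undefined"
        )
    return AttenuationCall(
        junction_index=junction_index,
        upstream_mean=up_mean,
        downstream_mean=float(down.mean()),
    )
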