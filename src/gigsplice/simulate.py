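"""Synthetic testis RNA-seq over multi-exon genes with gigantic introns.

The generator emits a gene model, a reference sequence, SAM-style reads and a
per-read ground-truth table.  Reads overlapping each exon 3' end are drawn
from a configurable mixture of the junction evidence classes seen in real
spliced alignments:

``spliced``
    skip from the donor to the canonical acceptor (mature mRNA),
``unspliced``
    contiguous alignment across the exon–intron boundary (nascent RNA),
``exon_other``
    skip from the donor to a non-canonical intronic acceptor (mis-splicing),
``backsplice``
    alignment ending at the donor in a soft clip whose sequence is the 5'
    prefix of an *earlier* exon (the linear-alignment signature of a
    back-splice / circular RNA junction),
``chimera``
    alignment ending at the donor in a soft clip of random sequence
    (library-preparation artifact).

Optionally the generator also emits mRNA-body reads at a target depth with a
transcription-attenuation point: downstream of a chosen junction only a
``retention`` fraction of transcripts continue, which both thins junction
reads and produces the read-depth drop the coverage module measures.

``simulate_cohort`` plants an intron-size effect: per-junction defect
probability follows ``logistic(a + b * ln(intron_length))`` with lengths drawn
log-uniformly, one mini-gene per junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alignment import AlignedRead
from .genemodel import Exon, GeneModel, junction_coords

__all__ = [
    "JunctionMix",
    "Attenuation",
    "SizeEffect",
    "SimConfig",
    "TruthRecord",
    "SimResult",
    "CohortJunction",
    "CohortResult",
    "simulate_gene",
    "simulate_cohort",
    "exon_five_prime_comparator",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
CATEGORIES = ("spliced", "unspliced", "exon_other", "backsplice", "chimera")


@dataclass(frozen=True)
class JunctionMix:
    """Per-junction category probabilities; must sum to 1."""

    spliced: float = 1.0
    unspliced: float = 0.0
    exon_other: float = 0.0
    backsplice: float = 0.0
    chimera: float = 0.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.spliced, self.unspliced, self.exon_other, self.backsplice, self.chimera)

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"mixture probabilities must be in [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"mixture probabilities must sum to 1: {probs}")


@dataclass(frozen=True)
class Attenuation:
    """Downstream of ``junction_index`` only ``retention`` of transcripts remain."""

    junction_index: int
    retention: float

    def __post_init__(self) -> None:
        if not 0 < self.retention <= 1:
            raise ValueError(f"retention must be in (0, 1], got {self.retention}")


@dataclass(frozen=True)
class SizeEffect:
    """Defect probability model: p = logistic(a + b * ln(intron_length))."""

    a: float = -6.0
    b: float = 0.55

    def p_defect(self, intron_length: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.a + self.b * math.log(intron_length))))


@dataclass
class SimConfig:
    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int]
    strand: str = "+"
    chromosome: str = "chrS"
    gene_id: str = "simgene"
    read_length: int = 250
    reads_per_junction: int | Sequence[int] = 2000
    mixes: JunctionMix | Sequence[JunctionMix] = field(default_factory=JunctionMix)
    backsplice_targets: dict[int, Sequence[tuple[int, float]]] = field(default_factory=dict)
    attenuation: Attenuation | None = None
    coverage_depth: float | None = None
    min_overhang: int = 1
    clip_length_range: tuple[int, int] = (11, 60)
    eo_min_offset: int = 20  # min distance of a mis-spliced acceptor from the donor
    intron_window: int | None = None  # sparse mode: random sequence only this far into introns
    duplicated_exons: tuple[int, int, int] | None = None  # (src, dst, prefix_len)
    gene_offset: int = 500
    seed: int = 0

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def n_junctions(self) -> int:
        return self.n_exons - 1

    def mix_for(self, junction: int) -> JunctionMix:
        if isinstance(self.mixes, JunctionMix):
            return self.mixes
        return self.mixes[junction - 1]

    def reads_for(self, junction: int) -> int:
        if isinstance(self.reads_per_junction, int):
            return self.reads_per_junction
        return int(self.reads_per_junction[junction - 1])

    def validate(self) -> None:
        if self.n_exons < 2:
            raise ValueError("need at least two exons to have a junction")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("need exactly one intron length per junction")
        if self.read_length < 2 * self.min_overhang:
            raise ValueError(
                "read_length too short to span a junction with the required overhang"
            )
        if not isinstance(self.mixes, JunctionMix) and len(self.mixes) != self.n_junctions:
            raise ValueError("one JunctionMix per junction required")
        for j in range(1, self.n_junctions + 1):
            if self.reads_for(j) == 0:
                continue
            mix = self.mix_for(j)
            if mix.backsplice > 0 and j == 1 and not self.backsplice_targets.get(1):
                raise ValueError(
                    "junction 1 cannot back-splice: no earlier exon exists as acceptor"
                )
            for b, _w in self.backsplice_targets.get(j, ()):
                if b >= j + 1:
                    raise ValueError(
                        f"back-splice acceptor exon {b} must be earlier than donor exon {j}"
                    )
        if self.attenuation is not None and not 1 <= self.attenuation.junction_index <= self.n_junctions:
            raise ValueError("attenuation junction out of range")
        clo, chi = self.clip_length_range
        if clo < 1 or chi < clo:
            raise ValueError(f"bad clip_length_range {self.clip_length_range}")


@dataclass(frozen=True)
class TruthRecord:
    junction_index: int | None  # None for mRNA-body reads
    category: str               # one of CATEGORIES, or "body"
    acceptor_exon: int | None = None  # planted back-splice acceptor


@dataclass
class SimResult:
    model: GeneModel
    reference: dict[str, str]
    reads: list[AlignedRead]
    truth: dict[str, TruthRecord]

    def truth_counts(self, junction: int) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for rec in self.truth.values():
            if rec.junction_index == junction:
                counts[rec.category] += 1
        return counts


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def exon_five_prime_comparator(model: GeneModel, reference: str, exon_index: int, k: int) -> str:
    """Forward-genomic k-mer adjacent to an exon's transcription 5' boundary.

    A donor-side soft clip produced by a splice to this exon's 5' end equals
    this slice in SAM (reference-forward) orientation: for + genes the first k
    bases of the exon; for - genes the last k genomic bases of the exon (the
    aligner stores the read reverse-complemented).
    """
    ex = model.exon_by_index(exon_index)
    k = min(k, ex.length)
    if model.strand == "+":
        return reference[ex.start : ex.start + k]
    return reference[ex.end - k : ex.end]


def _build_layout(config: SimConfig) -> GeneModel:
    """Place exons on the chromosome in transcription order."""
    spans: list[tuple[int, int]] = []
    pos = config.gene_offset
    for i, elen in enumerate(config.exon_lengths):
        spans.append((pos, pos + elen))
        if i < config.n_junctions:
            pos += elen + config.intron_lengths[i]
    if config.strand == "-":
        # transcription order descends genomically: exon 1 is the rightmost span
        spans = spans[::-1]
    exons = [Exon(index=i + 1, start=s, end=e) for i, (s, e) in enumerate(spans)]
    return GeneModel(
        gene_id=config.gene_id,
        chromosome=config.chromosome,
        strand=config.strand,
        exons=exons,
    )


def _build_reference(config: SimConfig, model: GeneModel, rng: np.random.Generator) -> str:
    """Random reference; optionally N-filled deep inside introns (sparse mode).

    Exon 5' comparator k-mers are kept pairwise distinct by rejection so clip
    matching is unambiguous by construction, except when ``duplicated_exons``
    deliberately plants a shared prefix.
    """
    lo, hi = model.span
    total = hi + config.gene_offset
    window = config.intron_window
    for _attempt in range(100):
        if window is None:
            seq = list(_random_bases(rng, total))
        else:
            seq = ["N"] * total
            seq[:lo] = _random_bases(rng, lo)
            seq[hi:] = _random_bases(rng, total - hi)
            for ex in model.exons:
                seq[ex.start : ex.end] = _random_bases(rng, ex.length)
            exons_genomic = sorted(model.exons, key=lambda e: e.start)
            for a, b in zip(exons_genomic, exons_genomic[1:]):
                left = min(window, b.start - a.end)
                seq[a.end : a.end + left] = _random_bases(rng, left)
                right = min(window, b.start - a.end - left)
                if right:
                    seq[b.start - right : b.start] = _random_bases(rng, right)
        ref = "".join(seq)
        if config.duplicated_exons is not None:
            src, dst, plen = config.duplicated_exons
            donor_seq = exon_five_prime_comparator(model, ref, src, plen)
            ex = model.exon_by_index(dst)
            chars = list(ref)
            if model.strand == "+":
                chars[ex.start : ex.start + len(donor_seq)] = donor_seq
            else:
                chars[ex.end - len(donor_seq) : ex.end] = donor_seq
            ref = "".join(chars)
        kmers = [exon_five_prime_comparator(model, ref, i, 16) for i in range(1, model.n_exons + 1)]
        dup_pair = set(config.duplicated_exons[:2]) if config.duplicated_exons else set()
        seen: dict[str, int] = {}
        clash = False
        for i, k in enumerate(kmers, start=1):
            if k in seen and not {seen[k], i} == dup_pair:
                clash = True
                break
            seen[k] = i
        if not clash:
            return ref
    raise RuntimeError("could not generate reference with distinct exon prefixes")


def _clip_matches_any_exon(clip: str, model: GeneModel, ref: str) -> bool:
    k = min(len(clip), 11)
    for i in range(1, model.n_exons + 1):
        cmpr = exon_five_prime_comparator(model, ref, i, k)
        if model.strand == "+":
            if clip[:k] == cmpr:
                return True
        else:
            if clip[-k:] == cmpr:
                return True
    return False


class _JunctionEmitter:
    """Builds reads of each category at one junction (strand-aware)."""

    def __init__(self, config: SimConfig, model: GeneModel, ref: str, junction: int,
                 rng: np.random.Generator):
        self.cfg = config
        self.model = model
        self.ref = ref
        self.j = junction
        self.rng = rng
        self.donor_exon = model.exon_by_index(junction)
        self.acceptor_exon = model.exon_by_index(junction + 1)
        self.d, self.a = junction_coords(model, junction)
        self.intron_len = model.introns[junction - 1].length
        self.window = (config.intron_window if config.intron_window is not None
                       else self.intron_len)
        self.window = min(self.window, self.intron_len)
        self.plus = model.strand == "+"

    def _uniform(self, lo: int, hi: int) -> int:
        if lo > hi:
            raise ValueError(
                f"junction {self.j}: read_length too short / exon or intron too small "
                f"for the requested geometry"
            )
        return int(self.rng.integers(lo, hi + 1))

    def spliced(self) -> tuple[int, list, str]:
        L, mo = self.cfg.read_length, self.cfg.min_overhang
        u = self._uniform(max(mo, L - self.acceptor_exon.length),
                         min(L - mo, self.donor_exon.length))
        v = L - u
        if self.plus:
            pos = self.d - u
            cig = [("M", u), ("N", self.intron_len), ("M", v)]
            seq = self.ref[pos : self.d] + self.ref[self.a : self.a + v]
        else:
            pos = self.a - v
            cig = [("M", v), ("N", self.intron_len), ("M", u)]
            seq = self.ref[pos : self.a] + self.ref[self.d : self.d + u]
        return pos, cig, seq

    def unspliced(self) -> tuple[int, list, str]:
        L, mo = self.cfg.read_length, self.cfg.min_overhang
        # m = exon-side bases; intron side must fit in the sequenced window
        m = self._uniform(max(mo, L - self.window), min(L - mo, self.donor_exon.length))
        pos = self.d - m if self.plus else self.d - (L - m)
        seq = self.ref[pos : pos + L]
        return pos, [("M", L)], seq

    def exon_other(self) -> tuple[int, list, str]:
        L, mo = self.cfg.read_length, self.cfg.min_overhang
        off = self.cfg.eo_min_offset
        u = self._uniform(max(mo, L - (self.window - off)),
                         min(L - mo, self.donor_exon.length))
        v = L - u
        delta = self._uniform(off, self.window - v)
        if self.plus:
            pos = self.d - u
            acc = self.d + delta
            cig = [("M", u), ("N", delta), ("M", v)]
            seq = self.ref[pos : self.d] + self.ref[acc : acc + v]
        else:
            acc = self.d - delta
            pos = acc - v
            cig = [("M", v), ("N", delta), ("M", u)]
            seq = self.ref[pos : acc] + self.ref[self.d : self.d + u]
        return pos, cig, seq

    def _clipped(self, clip: str) -> tuple[int, list, str]:
        L = self.cfg.read_length
        c = len(clip)
        u = L - c
        if u < self.cfg.min_overhang or u > self.donor_exon.length:
            raise ValueError(f"junction {self.j}: clip length {c} leaves no valid anchor")
        if self.plus:
            pos = self.d - u
            return pos, [("M", u), ("S", c)], self.ref[pos : self.d] + clip
        pos = self.d
        return pos, [("S", c), ("M", u)], clip + self.ref[self.d : self.d + u]

    def _clip_len(self) -> int:
        clo, chi = self.cfg.clip_length_range
        chi = min(chi, self.cfg.read_length - self.cfg.min_overhang, self.donor_exon.length)
        return self._uniform(clo, chi)

    def backsplice(self, acceptor_exon_index: int) -> tuple[int, list, str]:
        c = min(self._clip_len(), self.model.exon_by_index(acceptor_exon_index).length)
        clip = exon_five_prime_comparator(self.model, self.ref, acceptor_exon_index, c)
        return self._clipped(clip)

    def chimera(self) -> tuple[int, list, str]:
        c = self._clip_len()
        for _ in range(50):
            clip = _random_bases(self.rng, c)
            if not _clip_matches_any_exon(clip, self.model, self.ref):
                return self._clipped(clip)
        raise RuntimeError("could not generate a non-matching chimeric clip")


def _transcript_to_genomic(model: GeneModel, t_start: int, t_end: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to sorted genomic blocks."""
    blocks = []
    offset = 0
    for ex in model.exons:
        lo = max(t_start, offset)
        hi = min(t_end, offset + ex.length)
        if lo < hi:
            if model.strand == "+":
                blocks.append((ex.start + (lo - offset), ex.start + (hi - offset)))
            else:
                blocks.append((ex.end - (hi - offset), ex.end - (lo - offset)))
        offset += ex.length
    blocks.sort()
    return blocks


def _body_read(model: GeneModel, ref: str, t_start: int, read_length: int,
               read_id: str) -> AlignedRead:
    blocks = _transcript_to_genomic(model, t_start, t_start + read_length)
    cig: list[tuple[str, int]] = []
    seq_parts = []
    prev_end = None
    for (s, e) in blocks:
        if prev_end is not None:
            cig.append(("N", s - prev_end))
        cig.append(("M", e - s))
        seq_parts.append(ref[s:e])
        prev_end = e
    return AlignedRead(
        read_id=read_id,
        chromosome=model.chromosome,
        pos=blocks[0][0],
        cigar=tuple(cig),
        sequence="".join(seq_parts),
    )


def simulate_gene(config: SimConfig, *, reference: str | None = None) -> SimResult:
    """Emit (GeneModel, reference, reads, truth) for one gene.

    Per junction, ``reads_per_junction`` draws from the junction's category
    mixture; downstream of an attenuation point, junction read counts are
    binomially thinned by the retention factor.  If ``coverage_depth`` is set,
    mRNA-body reads are added from two transcript populations — full-length
    (fraction = retention) and truncated at the attenuation junction — so the
    exonic read-depth profile drops by the planted factor.  All sampling uses
    one seeded generator: identical config + seed gives identical output.

    Passing ``reference`` reuses a previously built reference chromosome so
    several conditions can be simulated against one shared genome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = _build_layout(config)
    ref = reference if reference is not None else _build_reference(config, model, rng)

    reads: list[AlignedRead] = []
    truth: dict[str, TruthRecord] = {}
    serial = 0

    for j in range(1, config.n_junctions + 1):
        n = config.reads_for(j)
        if config.attenuation is not None and j > config.attenuation.junction_index and n > 0:
            n = int(rng.binomial(n, config.attenuation.retention))
        if n == 0:
            continue
        mix = config.mix_for(j)
        counts = rng.multinomial(n, mix.as_tuple())
        emitter = _JunctionEmitter(config, model, ref, j, rng)
        targets = config.backsplice_targets.get(j)
        if targets is None:
            targets = [(b, 1.0) for b in range(1, j)]
        if counts[3] > 0 and not targets:
            raise ValueError(f"junction {j}: back-splice reads requested but no earlier exon")
        t_idx = np.array([t[0] for t in targets]) if targets else None
        t_w = None
        if targets:
            w = np.array([t[1] for t in targets], dtype=float)
            t_w = w / w.sum()
        for cat, n_cat in zip(CATEGORIES, counts):
            for _ in range(int(n_cat)):
                acceptor = None
                if cat == "spliced":
                    pos, cig, seq = emitter.spliced()
                elif cat == "unspliced":
                    pos, cig, seq = emitter.unspliced()
                elif cat == "exon_other":
                    pos, cig, seq = emitter.exon_other()
                elif cat == "backsplice":
                    acceptor = int(t_idx[rng.choice(len(t_idx), p=t_w)])
                    pos, cig, seq = emitter.backsplice(acceptor)
                else:
                    pos, cig, seq = emitter.chimera()
                rid = f"{config.gene_id}:j{j}:{serial:07d}"
                serial += 1
                reads.append(AlignedRead(rid, config.chromosome, pos, tuple(cig), seq))
                truth[rid] = TruthRecord(junction_index=j, category=cat, acceptor_exon=acceptor)

    if config.coverage_depth is not None:
        T = model.transcript_length()
        L = config.read_length
        if T <= L:
            raise ValueError("transcript shorter than read length; no body reads possible")
        retention = 1.0
        t_up = T
        if config.attenuation is not None:
            retention = config.attenuation.retention
            t_up = sum(model.exon_by_index(i).length
                       for i in range(1, config.attenuation.junction_index + 1))
        n_full = int(round(retention * config.coverage_depth * T / L))
        starts = rng.integers(0, T - L + 1, size=n_full)
        n_trunc = 0
        if retention < 1.0 and t_up > L:
            n_trunc = int(round((1 - retention) * config.coverage_depth * t_up / L))
            starts = np.concatenate([starts, rng.integers(0, t_up - L + 1, size=n_trunc)])
        for t0 in starts:
            rid = f"{config.gene_id}:body:{serial:07d}"
            serial += 1
            reads.append(_body_read(model, ref, int(t0), L, rid))
            truth[rid] = TruthRecord(junction_index=None, category="body")

    return SimResult(model=model, reference={config.chromosome: ref}, reads=reads, truth=truth)


@dataclass
class CohortJunction:
    intron_length: int
    p_defect: float
    truth_counts: dict[str, int]

    @property
    def defect_fraction(self) -> float:
        n = sum(self.truth_counts.values())
        return 1.0 - self.truth_counts["spliced"] / n if n else float("nan")


@dataclass
class CohortResult:
    junctions: list[CohortJunction]
    sims: list[SimResult]  # empty when emit_reads=False

    @property
    def intron_lengths(self) -> np.ndarray:
        return np.array([j.intron_length for j in self.junctions], dtype=float)

    @property
    def truth_defect_fractions(self) -> np.ndarray:
        return np.array([j.defect_fraction for j in self.junctions])


def simulate_cohort(
    n_junctions: int,
    size_effect: SizeEffect | None = None,
    seed: int = 0,
    length_range: tuple[float, float] = (2_000.0, 1_000_000.0),
    reads_per_junction: int = 200,
    read_length: int = 250,
    exon_length: int = 300,
    defect_split: tuple[float, float, float] = (0.5, 0.25, 0.25),
    intron_lengths: Sequence[int] | None = None,
    defect_probs: Sequence[float] | None = None,
    emit_reads: bool = True,
) -> CohortResult:
    """Per-junction cohort with an intron-size-dependent defect rate.

    Each junction is an independent three-exon mini-gene whose middle junction
    carries the drawn intron length; its defect probability is
    ``logistic(a + b*ln(length))`` (or ``defect_probs`` if given), split among
    unspliced / mis-spliced / back-spliced reads by ``defect_split``.  With
    ``emit_reads=False`` only category counts are sampled — the exact
    distribution of the full read-level simulation — which keeps large
    calibration studies (hundreds of replicate cohorts) cheap.
    """
    if size_effect is None:
        size_effect = SizeEffect()
    if abs(sum(defect_split) - 1.0) > 1e-9:
        raise ValueError("defect_split must sum to 1")
    rng = np.random.default_rng(seed)
    if intron_lengths is None:
        lo, hi = length_range
        lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_junctions))
        lengths = np.maximum(lengths.astype(int), read_length + 50)
    else:
        lengths = np.asarray(intron_lengths, dtype=int)
        if len(lengths) != n_junctions:
            raise ValueError("intron_lengths must have n_junctions entries")
    if defect_probs is not None and len(defect_probs) != n_junctions:
        raise ValueError("defect_probs must have n_junctions entries")

    junctions: list[CohortJunction] = []
    sims: list[SimResult] = []
    for i in range(n_junctions):
        L = int(lengths[i])
        p = float(defect_probs[i]) if defect_probs is not None else size_effect.p_defect(L)
        su, so, sb = defect_split
        mix = JunctionMix(
            spliced=1 - p, unspliced=p * su, exon_other=p * so, backsplice=p * sb
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if emit_reads:
            cfg = SimConfig(
                exon_lengths=[exon_length] * 3,
                intron_lengths=[400, L],
                gene_id=f"cohort{i:03d}",
                chromosome=f"chrC{i:03d}",
                read_length=read_length,
                reads_per_junction=[0, reads_per_junction],
                mixes=[JunctionMix(), mix],
                intron_window=600,
                seed=sub_seed,
            )
            sim = simulate_gene(cfg)
            sims.append(sim)
            counts = sim.truth_counts(2)
        else:
            sub = np.random.default_rng(sub_seed)
            drawn = sub.multinomial(reads_per_junction, mix.as_tuple())
            counts = dict(zip(CATEGORIES, (int(x) for x in drawn)))
        junctions.append(CohortJunction(intron_length=L, p_defect=p, truth_counts=counts))
    return CohortResult(junctions=junctions, sims=sims)
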