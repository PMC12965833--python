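# gigsplice

Splice-defect analysis for genes with gigantic introns.

Some genes — most famously the Y-linked axonemal dynein genes *kl-2*, *kl-3*
and *kl-5* of *Drosophila* testes — carry introns of hundreds of kilobases to
megabases while their coding exons total only ~15 kb. Splicing such introns is
hard, and when it fails the failure modes are visible in bulk RNA-seq
alignments: nascent reads running straight through an exon–intron boundary,
skips landing on the wrong acceptor, and soft-clipped fragments at exon 3'
ends whose clipped bases turn out to be the 5' prefix of an *earlier* exon —
the linear-alignment signature of back-splicing and circular RNA formation.
Downstream of a failed gigantic intron, read depth collapses: transcription
attenuates.

`gigsplice` is a tested, reusable implementation of that analysis for anyone
studying splicing of very large introns (hybrid sterility, spermatogenesis,
splicing-factor perturbations). It provides:

* **Junction read classification.** Every read overlapping an exon 3' end is
  assigned to exactly one category — *Spliced* (skip to the annotated
  acceptor), *Unspliced* (contiguous alignment across the boundary),
  *Exon-other* (skip to an unannotated acceptor), or *Exon-clipped* (soft
  clip strictly longer than 10 nt at the donor boundary). Reads matching
  known alternative isoforms are excluded.
* **Back-splice resolution.** Donor-side clips are compared to the 5' prefix
  of every other exon; a unique identical match to an earlier exon is a
  back-splice event (donor exon → acceptor exon, with read support);
  later-exon matches and ambiguous ties are reported separately.
* **Statistics.** Per-junction defect frequency
  `1 − spliced/all informative reads`; a binomial GLM (logit link) comparing
  spliced vs. non-spliced counts between conditions with Wald inference and
  Benjamini–Hochberg correction; intron-size binning on a natural-log scale
  with paired Wilcoxon signed-rank tests; Spearman correlation of intron size
  vs. defect frequency.
* **Coverage profiles.** Normalized read depth along the coding sequence and
  attenuation ratios (downstream/upstream mean depth) at each junction.
* **Conservation dot-plots.** Chunked Needleman–Wunsch identity grids with
  affine gaps (open −10, extend −0.5).
* **A ground-truthed simulator.** Synthetic testis-like RNA-seq over
  configurable gene models: per-junction category mixtures, planted
  back-splice acceptors, logistic intron-size effects, and transcription
  attenuation — every read carries a truth record, so classifier recovery,
  statistical power and type-I error are all measurable.

## Worked example

Simulate a six-exon gene in which junctions 2–5 carry a defective mixture
(55% spliced, 25% unspliced, 5% mis-spliced, 12% back-spliced, 3% chimeric
clips), then classify junction 4 and resolve its clipped reads:

```python
from gigsplice import (
    SimConfig, JunctionMix, simulate_gene, tally_junction,
    resolve_clips, backsplice_fraction, defect_frequency,
)
from gigsplice.classify import Category, classify_read

mix = JunctionMix(spliced=0.55, unspliced=0.25, exon_other=0.05,
                  backsplice=0.12, chimera=0.03)
cfg = SimConfig(
    exon_lengths=[400] * 6,
    intron_lengths=[600, 900, 1500, 700, 1100],
    mixes=[JunctionMix()] + [mix] * 4,
    reads_per_junction=1000,
    seed=42,
)
sim = simulate_gene(cfg)

tally = tally_junction(sim.reads, sim.model, 4)
print(f"junction 4: {tally.n_spliced} spliced, {tally.n_unspliced} unspliced, "
      f"{tally.n_exon_other} exon-other, {tally.n_exon_clipped} exon-clipped")
print(f"defect frequency: {defect_frequency(tally).value:.3f}")

clipped = [r for r in sim.reads
           if classify_read(r, sim.model, 4) is Category.EXON_CLIPPED]
res = resolve_clips(clipped, sim.model, sim.reference[cfg.chromosome], 4)
summ = backsplice_fraction(tally, res)
print(f"clipped fraction: {summ.clipped_fraction:.1%}, "
      f"back-spliced of clipped: {summ.assigned_of_clipped:.1%}")
for event in res.events:
    print(f"  exon {event.donor_exon_index} -> exon {event.acceptor_exon_index}: "
          f"{event.support} reads")
```

Output:

```
junction 4: 541 spliced, 271 unspliced, 44 exon-other, 144 exon-clipped
defect frequency: 0.459
clipped fraction: 14.4%, back-spliced of clipped: 78.5%
  exon 4 -> exon 1: 38 reads
  exon 4 -> exon 2: 34 reads
  exon 4 -> exon 3: 41 reads
```

The tally recovers the planted mixture (note the 1000 reads at this junction:
541/1000 spliced vs. the planted 55%); the 144 clipped reads split into 113
back-splice reads assigned — every one to its true planted acceptor — and 31
chimeric clips left unassigned, so 78.5% of clipped reads are back-splices.
The defect frequency 0.459 is `1 − 541/1000`.

The same analysis runs from the shell: `gigsplice simulate`, `classify`,
`backsplice`, `coverage`, `dotplot`, and `gigsplice run-all --config cfg.yaml`
for a full two-condition (e.g. parental vs. hybrid) comparison producing
tally/event/comparison/bin/coverage TSVs, figures, and a JSON summary, all
reproducible byte-for-byte from the config seed.

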