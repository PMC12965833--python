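# Methods

## The measurement problem

At every exon 3' end (the splice donor), bulk RNA-seq reads that overlap the
boundary carry direct evidence about what happened to the downstream intron.
`gigsplice` partitions those reads into four mutually exclusive categories and
builds all downstream statistics on the resulting counts:

| category | alignment evidence |
|---|---|
| Spliced | skip (`N` CIGAR op) from the donor to the annotated downstream acceptor |
| Unspliced | one contiguous aligned block crossing the exon–intron boundary (nascent RNA) |
| Exon-other | skip from the donor to any other position (mis-splicing or recursive-splicing intermediates) |
| Exon-clipped | alignment ends exactly at the donor in a soft clip **strictly longer than 10 nt** |

Reads whose skip lands on an acceptor belonging to a known alternative
isoform or overlapping gene are excluded from the tally altogether, and reads
ending at or before the donor with no evidence beyond it are not informative
and are not counted.

### Classifier conventions

* **Clip-first precedence.** A read with a ≥ 11 nt soft clip sitting exactly
  at the donor boundary is Exon-clipped regardless of any other signal: the
  clip *is* the junction evidence on the donor side.
* **Short clips (1–10 nt)** are treated as aligner noise. Such a read is
  classified by its remaining evidence (skip or boundary-crossing block) and
  becomes not-informative if there is none. The 10/11 boundary is exposed as
  `ClassifierParams.min_clip_len` (default 11, i.e. clip > 10 nt).
* **Clip position is strict.** The clip must start exactly at the donor
  boundary; no aligned intronic bases may precede it (slack fixed at 0).
* **`min_overhang`** (default 1) is the number of query bases of evidence
  required beyond the donor for an unspliced call.
* **Strand.** Read orientation is ignored; only the gene's strand defines
  donor/acceptor. On minus-strand genes the donor sits at the genomic *right*
  edge of a skip and the donor-side clip is the alignment's left soft clip
  (SAM stores sequences in reference-forward orientation).

### Back-splice resolution

Each donor-side clip is compared — donor-adjacent end first, in
transcription orientation — with the 5' prefix of every other exon of the
gene, demanding identity by default (`max_clip_mismatches = 0`; real-data
users can relax it). A unique best match to an **earlier** exon yields a
back-splice event donor → acceptor, the signature of circular RNA formation.
A unique match to a **later** exon is reported as a distal-forward-splice
candidate and never called back-splicing. Ties (e.g. duplicated exon
prefixes) are flagged ambiguous, counted but never assigned; base-level
polymorphism phasing of duplicated exons is deliberately out of scope — the
ambiguity flag plus the simulator's duplicated-exon mode cover that case.
`backsplice_fraction` reports, per donor: clipped reads / all informative
reads, assigned back-splice support / all informative reads, and the
per-acceptor breakdown.

## Statistics

* **Defect frequency** at a junction is `1 − n_spliced / n_total` over the
  four informative categories. An alternative "splicing efficiency"
  statistic, `spliced / (spliced + unspliced)`, restricts the denominator to
  reads with an unambiguous mature/nascent call; it is exposed as
  `splicing_efficiency` but the defect frequency is the primary statistic
  throughout (the two are not interchangeable once clipped or mis-spliced
  reads are common).
* **Per-junction group comparison** is a binomial GLM with logit link of
  (spliced, non-spliced) counts on a condition indicator, i.e. logistic
  regression on the aggregated 2×2 table, with a two-sided **Wald** test on
  the group log-odds coefficient. Replicates are pooled per condition before
  fitting (a χ²/df > 4 heterogeneity check across replicates emits an
  overdispersion warning). When any pooled cell is below 5, or the fit is
  separated (|coefficient| > 30 or non-finite p), inference falls back to the
  two-sided Fisher exact test and the effect becomes a Haldane-corrected log
  odds ratio — this keeps degenerate tables (0/100 vs. 100/0) testable.
  Note the Wald p agrees with the Pearson chi-square p closely (≈ few
  percent) near the null on well-filled tables but can differ by an order of
  magnitude at strong effects, where Wald and score statistics genuinely
  diverge; the implied z statistics stay within ~15%.
* **Multiple testing.** Benjamini–Hochberg, applied within two separate
  families: all junction-level GLM p-values of one comparison run, and all
  bin-level Wilcoxon p-values of one binned test.
* **Intron-size binning.** Bin label = ⌊ln(intron length)⌋ (natural-log
  scale). Per bin, a paired two-sided Wilcoxon signed-rank test compares the
  junction-wise defect frequencies of the two conditions; zero differences
  are dropped, the exact null distribution is used below 25 non-zero pairs
  and the normal approximation above; bins with fewer than 2 pairs are
  skipped with a warning. Intron lengths count assembled sequence only —
  assembly gaps are carried as a flag of unknown extra length and never added.
* **Size–defect association** is Spearman rank correlation (tie-corrected p)
  of intron length vs. defect frequency, requiring ≥ 3 junctions and
  non-constant vectors.

## Coverage and attenuation

Depth is accumulated from aligned blocks only (skips and clips contribute
nothing), restricted to exonic positions, and laid out in transcription order
so the x-axis is position along the coding sequence with introns collapsed.
Raw per-base values are reported (no smoothing; an optional window mean is a
display choice, off by default). Two-stage normalization: divide by the
sample's total aligned bases (library-size proxy — the profile is invariant
to sequencing depth, verified by read duplication), then scale so the first
exon's mean is 1 for cross-sample display.

The attenuation ratio at junction *j* is the mean normalized depth over exons
downstream of *j* divided by the mean upstream. Because reads have finite
length, depth ramps over roughly one read length at the junction and at the
transcript ends; the estimator therefore takes a `trim` parameter (coding-
sequence positions excluded adjacent to the junction and at both transcript
ends; one read length is the recommended value and the pipeline default).
With trimming, planted retention factors 0.1–0.9 are recovered within ±0.02
at 100× depth. Attenuation is a descriptive ratio at annotated junctions, not
a changepoint test.

## Conservation dot-plots

Both sequences are cut into fixed-size chunks (default 500 nt, configurable;
minimum 50) and every chunk pair is globally aligned (Needleman–Wunsch) under
affine gap penalties — open −10, extend −0.5 — with match +5 / mismatch −4,
an EDNAFULL-style nucleotide scoring exposed as a configurable matrix. Gap
semantics: the first gap position costs the open penalty, each further
position the extension penalty; end gaps are penalized like internal gaps.
Cell identity is matches / alignment columns × 100. Because co-optimal
alignments can differ in identity, each pair is aligned in a canonical
(lexicographic) argument order, making `dotplot(a, b)` exactly the transpose
of `dotplot(b, a)`. Rendering maps ≤ 50% identity to white and 100% to black,
linearly in between.

## The simulator

`simulate_gene` emulates testis total-RNA sequencing over a multi-exon gene:
single-end reads of 250 nt by default (large-intron studies favor long
paired-end libraries, e.g. 250 × 250 bp; pairing adds nothing at the junction
level, so only one mate is modeled), constant base quality, no sequencing
errors or PCR duplicates. Per junction, a configurable number of reads is
drawn from a five-way category mixture:

* *spliced* reads place a skip from the donor to the canonical acceptor with
  a uniformly drawn donor-side overhang;
* *unspliced* reads align contiguously across the boundary, uniformly placed
  with at least `min_overhang` bases on each side;
* *exon-other* reads skip to a uniformly drawn intronic acceptor ≥ 20 nt
  downstream of the donor;
* *backsplice* reads end at the donor in a soft clip (length uniform in
  11–60 nt) whose sequence is exactly the 5' prefix of a planted earlier
  exon — donor-side evidence only, as a linear aligner would report it; no
  circular-molecule model;
* *chimera* reads carry a random clip, rejection-sampled to match no exon
  prefix.

Reference sequences are random with exon-5' 16-mers kept pairwise distinct by
rejection, so clip matching is unambiguous by construction; a
`duplicated_exons` mode deliberately plants a shared prefix to exercise the
ambiguity path. In sparse mode (`intron_window`), only the first/last window
of each gigantic intron is sequence and the deep interior is `N` — reads
never align there, which keeps megabase introns cheap.

**Attenuation** (junction *k*, retention *r*): junction read counts
downstream of *k* are binomially thinned by *r*, and optional mRNA-body reads
are drawn from two transcript populations — full-length (proportional to
*r*) and truncated at *k* — so the exonic depth profile drops by the planted
factor. **`simulate_cohort`** draws per-junction intron lengths log-uniformly
(default 2 kb–1 Mb, the gigantic-intron regime) and sets each junction's
defect probability to `logistic(a + b·ln L)` (defaults a = −6, b = 0.55,
spanning ≈ 0.15 at 2 kb to ≈ 0.85 at 1 Mb), split 50/25/25% among
unspliced / exon-other / backsplice; each junction is an independent
three-exon mini-gene. With `emit_reads=False` only category counts are
sampled — distributionally identical to the read-level path (cross-checked in
tests) — which keeps hundreds-of-replicates calibration studies at sub-second
cost. All sampling flows through one seeded generator: identical config and
seed reproduce the SAM and truth table byte for byte.

### What the simulator does not model

Sequencing error, indels within reads, mapping ambiguity/multi-mappers,
fragment-length and GC biases, cell-population structure (e.g. early
spermatocytes that have not yet transcribed the downstream exon inflate
unspliced fractions in real testes), and genuinely circular molecules
(acceptor-side back-splice evidence). Passing tests therefore demonstrate
correctness of the *computation* — category recovery, unbiased fraction and
ratio estimation, calibrated tests — on clean alignments, not robustness to
aligner artifacts; on real data the mapping-quality filter, the clip-mismatch
allowance and the known-alternative-acceptor list are the knobs that absorb
that noise.

## Problem sizes and numerical choices

Validation studies use sizes at which the checked quantities are
statistically decisive: 8-exon genes at 2,000 reads per junction for
classifier recovery (category fractions within 3 binomial SD), 60-junction
cohorts at 200 reads per junction over 20 seeds for size-effect power and 200
count-level replicates for null calibration, 40 junctions per bin for the
binned Wilcoxon, and 100× depth with 3 kb exons for attenuation recovery.
Seeds are fixed in tests and derived from the single `--seed` in the
acceptance script. TSV floats are written at six significant digits;
p-values are reported unclipped; GLM separation is guarded as described
above. A k-mer prescreen for dot-plot chunks was considered and rejected:
cells must be exact, and the Biopython aligner is already fast at the sizes
used.

## Known limitations

One transcript model per gene (the gigantic Y-linked genes are effectively
single-isoform; alternative isoforms enter only through the excluded-acceptor
set). Hard-clipped alignments are rejected rather than rescued (clip sequence
is required for back-splice matching). Exon-other reads are counted but not
interpreted — distinguishing erroneous splicing from recursive splicing would
need acceptor-motif analysis. Attenuation has no significance test. The
binomial GLM pools replicates; a beta-binomial extension would be the natural
upgrade where biological replication is rich.
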