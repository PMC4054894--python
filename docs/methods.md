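# Methods

This note documents the models and procedures implemented in
`photosplice`, the assumptions behind them, the parameters that matter,
and what the synthetic-data validation does and does not establish.

## Gene models and coordinates

All intervals are 0-based half-open internally; GFF3 I/O converts
from/to 1-based closed coordinates.  One transcript model per gene — the
annotation's primary transcript (first mRNA by identifier) — defines the
exon/intron structure that the whole event space is built against;
additional annotated isoforms are ignored for counting.  This is a
deliberate simplification: the AS events of interest are deviations from
a reference structure, and a single reference per gene keeps the
supporting/non-supporting contrasts unambiguous.  The convention is
recorded in the run manifest.  Introns are the maximal gaps between
consecutive exons, numbered in ascending genomic coordinate regardless
of strand (so "intron 1" of a minus-strand gene is its transcript-last
intron); donor/acceptor sites follow the strand.

## Read counting

Only primary alignments are counted; paired-end mates count as two
independent reads, and `total_mapped` counts mates separately.  Aligned
blocks are derived from the CIGAR string with only `N` operations
opening a junction (deletions extend a block).  A read contributes to
every exon and every intron any of its blocks overlaps by ≥ 1 nt, with
no fractional assignment — the downstream chi-square contrast needs raw
tallies, not expectation-maximized ones.  A gap whose two ends exactly
match an annotated junction increments the exon-pair junction table
(non-adjacent pairs record exon-skipping junctions); a gap landing
within ±100 nt of an annotated junction at both ends but differing at
one or both increments the shifted-junction table with signed
donor/acceptor offsets expressed in transcript orientation (positive =
into the intron).  The ±100 nt window bounds the AltD/AltA search space;
it is configurable (`shift_tolerance`).  No minimum junction-overhang
is imposed (≥ 1 nt); reads overlapping two genes count toward both, as
no disambiguation rule is defensible without isoform inference.

`RPKM = 1e9·C_exon/(N·L_exon)` uses, as `C_exon`, the number of
*distinct* reads overlapping the gene's exon model; the same quantity
serves as the "reads mapped to exon regions" input of stepwise filter 1
and as the non-supporting count of IR events, so the three uses are
mutually consistent.  `IPKM` applies the same formula to intron reads
and intron length.

## Event calling and stepwise filters

IR events contrast per-intron intronic reads against the gene's exon
reads (a proxy for total transcripts); ES events contrast
exon-skipping junction reads against reads on the skipped exon; Alt*
events contrast shifted-junction reads against zero-shift reads at the
same junction, classified AltD/AltA/AltDA by which end moved.  ES event
identity includes the bridging exon pair (`(i, skipped, j)`), so two
different bridges skipping the same exon are distinct events.

Three stepwise filters prune candidates, each threshold defaulting
to 2 reads with counts summed over all samples of a condition group:
(1) gene exon reads ≥ 2; (2) spliced reads at the junction(s) of the AS
site ≥ 2 — for IR the zero-shift junction across the retained intron
(per-intron, not any gene junction: the stricter, more local reading),
for ES the skipping junction, for Alt* the shifted junction itself;
(3) supporting reads ≥ 2.  For Alt* events filters 2 and 3 coincide by
construction.

## Light-responsiveness test

Each filtered event is tested with the 2 × k chi-square homogeneity
statistic over supporting/non-supporting counts across the k
conditions of a group (default k = 3: dark, 1 h, 4 h), df = k − 1, no
continuity correction.  Significance is the raw *P* < 0.001 threshold;
a Benjamini–Hochberg q-value column is emitted for users but does not
drive the significance flag, keeping fidelity to the original
single-threshold analysis while making a corrected column available.
Tables with a zero row or column margin are flagged untestable and
excluded from ranking rather than assigned p = 1, which would otherwise
inflate the non-significant pool.  A goodness-of-fit variant that tests
light conditions against the dark-derived supporting proportion is
available (`test_method="gof_vs_baseline"`); the homogeneity test is
the default because it yields a single symmetric P value per event.

Ranking is by ascending p, then descending chi2, then (gene, locus) —
a total order with deterministic tie-breaking, recorded in the
manifest.  Relative IR is `(IPKM/RPKM)_condition / (IPKM/RPKM)_dark`;
conditions with zero RPKM, or events with a zero dark ratio, are
reported missing rather than clamped.  Heat-map-ready profiles divide
each IR and gene-expression series by its row mean; zero-mean rows are
excluded and logged.

Two statistical caveats are worth knowing.  First, with paired-end
data the two mates of one fragment are counted as independent reads,
which overdisperses counts relative to the binomial sampling the
chi-square assumes; at the default simulation conditions this inflates
the empirical false-positive rate at *P* < 0.001 to roughly 1–2% on
non-responsive introns (still within the pipeline's validated bound of
2%).  Second, with expected supporting counts below ~10 the asymptotic
chi-square tail is approximate; the stepwise filters remove the worst
cases but do not eliminate this.

## PTC annotation

For each IR event the single-intron-retention isoform is rebuilt from
the genome in transcript orientation and translated codon-by-codon from
the annotated start.  A PTC is **any** in-frame stop strictly upstream
of the authentic stop codon; no 50-nt exon-junction NMD rule is
applied, so calls are "potential PTC" in the weakest defensible sense.
The call records whether the stop codon starts inside the retained
intron or downstream (frameshifted exonic sequence included).  Introns
entirely upstream of the CDS cannot frameshift the ORF; they are
reported `has_ptc = False` and flagged uORF candidates, since retained
5'-UTR introns can create upstream ORFs — evaluating those is out of
scope.  Genes without an annotated CDS are skipped and logged.

## Motif analysis

Flank regions of the top-ranked retained introns: introns longer than
the 200-nt flank yield a donor-centered and an acceptor-centered region
(200 nt exonic + 200 nt intronic each, exonic side truncated at the
adjacent exon boundary and logged); shorter introns yield one merged
region (whole intron plus up to 200 nt of each adjacent exon).  The
control set is a seeded uniform sample of non-significant IR events,
extracted by the same rules; a per-sequence mononucleotide shuffle of
the sample set is emitted as a discovery background but is not part of
the enrichment contrast, which is exactly the 2 × 2 sample/control ×
hit/not-hit Fisher's exact test (one-sided, enrichment direction) on
sequences with ≥ 1 motif occurrence.  Mononucleotide (not dinucleotide)
shuffling was chosen as the simplest composition-preserving null.

Motif models are inputs: an IUPAC consensus is matched exactly
(overlapping windows allowed), or a PWM is scanned with a hit threshold
of per-window match p ≤ 1e-4 under a uniform background, computed
exactly by dynamic programming over the discretized score distribution
(MAST-like; the threshold is configurable since no single published
cutoff exists).  Scanning is single-strand in transcript orientation —
the motifs are exonic elements on pre-mRNA.  Positional profiles bin
hit starts into 20-nt windows at −200..+200 around each splice site
(position 0 = first base across the junction; for donor regions the
exonic side is negative, for acceptor regions positive); merged
short-intron regions carry no single anchor and are excluded.  The
GAA-repeat consensus motifs `[GC]AAGAAG` and `[GC]AAG[AGC]AG[GA]` ship
as packaged defaults.

## Synthetic data

The generator emulates the target study design: one chromosome of
alternating-strand multi-exon genes (default 300 genes, 4–6 exons of
150–300 nt, introns of 380–560 nt, 500-nt spacers), stop-free CDSs with
60-nt UTRs, GT..AG introns; conditions D/L1/L4 with per-gene expression
drawn lognormally around 400 fragments per sample (~55× coverage) and
optional per-condition multipliers; 30 responsive introns with
retention 0.02 in darkness and 0.30 under light against a background
retention of 0.02 everywhere; 100-nt paired-end reads from 230-nt
fragments placed uniformly on the chosen isoform; the GAA motif
overwritten into the exonic donor flank of 80% of responsive vs 5% of
non-responsive introns; optional alternative-donor introns emitting
junction-shifted spliced reads.  Each fragment retains at most one
intron (drawn per-intron Bernoulli, one winner kept), alignments are
written directly with correct gapped CIGARs, and every read can carry a
truth record tracing it to its gene and isoform.

The intron and exon length defaults were set, before any end-to-end
validation was run, from an explicit bias analysis of the IPKM/RPKM
retention estimator: interval-overlap counting inflates intron read
counts by roughly `(L_intron + read − 1)/L_intron` while the longer
retained transcript deflates per-base density, and the two effects
cancel to first order when intron length is ~2–2.5× the exon length at
this fragment size.  Under these defaults the estimator recovers
planted retention with a median relative error of ~5–13% across seeds
for introns with ≥ 100 intronic reads; the consistency check is on the
*median* across qualifying introns because single-intron counts at the
100-read threshold carry ~10% Poisson noise, so a per-intron bound
would measure sampling noise rather than estimator bias.  Much shorter
introns (≲ 200 nt) would need an overhang-corrected estimator — a known
limitation of the IPKM definition, not of the simulation.

What the simulation does **not** model: sequencing errors and quality
(alignment is bypassed), positional/GC bias, multi-isoform mixtures,
multi-mapped reads, and novel junctions outside annotated gene models.
Passing the validation therefore demonstrates correctness of the
bookkeeping and the statistical machinery under the stated sampling
model, not robustness to alignment artifacts in real libraries.

## Determinism and numerics

Every random choice (simulation, control-region sampling, shuffling)
derives from explicit integer seeds; reruns with the same configuration
produce byte-identical outputs (no timestamps are written, floats are
formatted with fixed precision, and all table iteration is over sorted
keys).  Ties in ranking are broken lexicographically.  Degenerate
inputs — empty tables, zero margins, zero baselines, zero-mean
profiles, missing CDSs — are flagged or excluded explicitly rather than
coerced.

## Validation problem sizes

The shipped validation uses 2×3 tables with entries up to 500 (1,000
random tables) for the chi-square cross-check; all 2×2 tables with
grand total ≤ 40 (~134,000 tables) for the Fisher cross-check; 2,000
count-level non-responsive events for the type-I bound; the default
300-gene / 30-responsive-intron study (~730,000 alignments across
three conditions) for recovery; a 20–25-gene study with per-read truth
for exact count-table equality and rerun determinism; 500 + 500
flank-region sets for motif recovery; and 200 random-intron isoforms
per frame class against the translation oracle.
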