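# Methods

This note documents the models, parameters, and numerical choices behind
isoscape, and what the synthetic-data generator does and does not emulate.

## Coordinates and data model

All genomic coordinates are 0-based half-open on the forward reference
strand; GFF3 I/O converts from 1-based inclusive at the boundary, BED and
RepeatMasker query coordinates are converted on read. Minus-strand
transcripts keep exons stored in genomic order; orientation is applied
where a transcript-sense view is needed (spliced-sequence extraction,
transcript-coordinate projection, motif windows). Missing
`identity`/`coverage` GFF3 attributes default to 1.0, i.e. curated input
passes the quality filter.

## Isoform collapse

Filter: keep iff identity ≥ `min_identity` (default 0.90) AND coverage ≥
`min_coverage` (default 0.85); both thresholds inclusive.

Merge rule: two multi-exon transcripts are redundant iff same chromosome
and strand, identical intron chains, and 3′ termini equal within
`end3_tolerance` (default 0 bp — no slack unless the user asks for it).
Because all internal exon boundaries are determined by the intron chain,
this is exactly "identical everywhere except the 5′ boundary of the
5′-terminal exon". Single-exon transcripts merge iff same strand, shared 3′
terminus (within tolerance) and overlapping spans; multi- and single-exon
transcripts never merge. Grouping is the transitive closure of the pairwise
relation (union–find over transcripts bucketed by chromosome/strand/intron
chain), which makes the partition independent of input order. The
representative is the member reaching furthest 5′ (ties: longest, then
lexicographic id). When no `gene_id` is present, loci for the
isoforms-per-locus histogram are formed by single-linkage clustering of
same-strand exon-overlapping representatives.

## AS-event classification

Events are extracted pairwise, AStalavista-style, then deduplicated —
not from a global splice graph — because pairwise bubbles are auditable by
hand. Anchors are (position, kind) boundary pairs present in both
transcripts, where kind is exon-start or exon-end; transcript termini count
as pseudo-anchors only when both termini coincide exactly, so truncation
artifacts are never called AS events. Between each pair of consecutive
anchors, the interior boundary lists of the two transcripts are compared;
if they differ the region is classified:

* one side empty, flanks exon-end→exon-start, other side complete exon(s):
  **ES** (one or more skipped exons);
* one side empty, flanks exon-start→exon-end, other side exactly one
  intron: **IR** (two or more retained introns in one exon → COMPLEX);
* both sides a single differing boundary of the same kind: **A5S** when the
  differing site is the donor, **A3S** when it is the acceptor, with
  donor/acceptor defined on the transcribed strand (so the genomic kind
  flips with strand);
* both sides exactly one internal exon, non-overlapping: **MEE**
  (overlapping alternative exons → COMPLEX);
* anything else: **COMPLEX**, listed but excluded from the five-type tally
  rather than force-fitted.

Deduplication key: (type, chromosome, strand, flanks, variant
coordinates). Two useful symmetries follow from the definitions and are
tested: flipping strand at fixed coordinates swaps A5S↔A3S and preserves
ES/IR/MEE; mirroring all coordinates and flipping strand preserves the
transcribed structure and therefore every event type.

## Motif matrices and polyA signals

Position frequency matrices are anchored at the splice junction in
transcribed-strand orientation, with offsets that skip zero: +k is the k-th
base downstream of the junction point, −k the k-th upstream. For donors the
junction is the exon|intron boundary (+1/+2 = first two intron bases,
canonically GT); for acceptors the intron|exon boundary (−2/−1 = last two
intron bases, canonically AG). Default windows: donor (−3, +6), acceptor
(−10, +3). Minus-strand windows are complemented and read in transcribed
order. Sites whose window leaves the chromosome are skipped and counted.
A TSS-anchored matrix is provided with a caller-chosen window; no consensus
claim is attached to it (the appropriate window is data-dependent and the
library makes no default recommendation beyond (−30, +10)).

PolyA-signal ranking scans the 3′-terminal window (default 50 bp) of each
transcript 3′→5′ and counts the first hit from a 12-hexamer canonical set
(AATAAA first); each transcript contributes at most one hexamer, no-hit
transcripts count as "none".

## Coding potential and lncRNA calling

`find_longest_orf` scans the three forward frames only — full-length cDNA
protocols are orientation-resolved, so antisense frames are not searched.
It returns the longest ATG→stop ORF (ties: 5′-most start); `min_codons` is
the minimum protein length including the initial Met. If no stop-terminated
ORF qualifies, the longest open ORF reaching the final complete codon is
returned with `has_stop=False`. Codons containing N never act as start or
stop.

Three scorers, each a flag-tunable default:

* **ORF length**: coding iff a stop-terminated ORF of ≥ 100 codons exists.
  100 codons is the community default for such filters.
* **Fickett TESTCODE**: coding iff score ≥ 0.95 (the classical "probably
  coding" boundary). The published position/composition lookup tables are
  embedded as constants; the position parameter for base B is
  max/(min + 1) over the three codon positions, the composition parameter
  is B's overall fraction, and the score is the sum of the eight weighted
  table lookups.
* **Hexamer usage**: log(f_coding/f_noncoding) per hexamer with
  pseudocount 1, counting coding ORFs in frame (step 3) and noncoding
  sequences in all frames (step 1). A transcript's score is the mean
  log-ratio over the in-frame hexamers of its longest ORF; > 0 ⇒ coding.
  ORFs shorter than 25 codons score 0 (treated as no signal): the mean of
  so few hexamer log-ratios is dominated by sampling noise, and scoring
  them would flip a coin on genuinely noncoding transcripts. When no
  labels are given, training labels are bootstrapped from the ORF-length
  rule; `HexamerCodingModel` also accepts explicit labels
  (scikit-learn `fit(X, y)`).

Intersection rule: lncRNA iff length ≥ `min_lnc_len` (default 200 nt, the
community convention) AND every configured scorer says noncoding. Adding a
scorer can therefore only shrink the lncRNA set. The coding set is the
complement, so the two sets always partition the input.

## TE exonization

Repeat features are projected exon-by-exon into spliced-transcript
coordinates (minus-strand transcripts mirrored so coordinates run 5′→3′);
fragments abutting across a splice junction are merged. A record is emitted
per (transcript, repeat feature) whose exonic overlap is ≥ `min_overlap`
(default 10 bp — a small floor that suppresses 1–2 bp alignment artifacts),
and a transcript is TE-exonized iff it has at least one record; with
fragments well above the floor, per-feature and total-overlap gating
coincide. Region labels intersect the fragment with [0, orf.start) →
FIVE_UTR, [orf.start, orf.end) → ORF, [orf.end, length) → THREE_UTR for
coding transcripts (a fragment spanning a boundary counts in every region
it touches, so region tallies are deliberately not additive), and
NONCODING_EXON for lncRNAs.

Transposase-coding classification is an operationalization: a coding
TE-transcript is transposase-coding iff some record covers ≥ 50% of the ORF
or a transposase-flagged family's fragment covers the ORF start; the flag
comes from repeat-library metadata. Both the threshold and the flag set are
caller-configurable, and transposase transcripts are excluded from the
UTR/ORF region tallies (they are reported separately).

Statistics: the two-sample proportion test uses the pooled-variance z
statistic with a two-sided normal p-value; z² equals the Pearson chi-square
statistic of the corresponding 2×2 table (tested to 1e-9), and degenerate
pooled proportions (0 or 1) return z = 0, p = 1. Enrichment uses the
upper-tail hypergeometric probability P[X ≥ k | N, K, n] per term (terms
with zero study hits are skipped) with Benjamini–Hochberg adjustment across
tested terms.

Transcripts classified coding by the intersection rule but lacking any ORF
(possible for short ATG-free sequences that a scorer nonetheless flags)
cannot be region-localized; the pipeline excludes them from TE annotation
and reports their count (`n_coding_without_orf`) rather than guessing a
label.

## The synthetic-data generator

The generator emulates the input a long-read pipeline sees after genome
mapping, with exact truth tables. Defaults define the stated world:
200 genes, 2–8 exons of 80–400 bp, introns 60–2000 bp, 60% coding genes,
degraded-copy probability 0.5, polyA-signal probability 0.8, 25 planted AS
events (5 per type), TE insertion rate 0.8 per gene (70% exonic), and 6 TE
families of 100–600 bp with two transposase families. Coding-gene TE
fragments land in 5′UTR/3′UTR/ORF with weights 0.26/0.69/0.05 and ~5% of
TE-carrying coding genes are transposase genes — the region mix and
transposase rate observed in real TE-exonization surveys.

Construction happens in a gene-local plus-strand frame; minus-strand loci
are reverse-complemented wholesale, which guarantees GT…AG introns and
sense ORFs on the transcribed strand by construction. Planted AS events are
realized as exactly one structural edit of a base isoform (skip an internal
exon; retain an intron; move a donor/acceptor 9–30 bp with a planted GT/AG
at the new site; or substitute a disjoint exon planted inside an intron
with its own splice dinucleotides). Event host genes are chosen among
noncoding genes and receive no TE insertions, so each derived isoform's
coding and TE truth labels are unambiguous. 5′-degraded copies trim the
5′-terminal exon by 10–40 bp, never into a planted ORF or TE fragment.

Coding transcripts carry one ATG→stop ORF of ≥ 100 codons with GC3-biased
codon usage; their 5′UTRs are scrubbed of ATG so the planted ORF is the
found ORF. Noncoding transcripts are dinucleotide-preserving
(Altschul–Erickson Euler-path) shuffles of coding-like proto sequences —
matched composition, destroyed frame and position structure. The generator
validates its own truth labels: a coding gene is re-drawn until the planted
ORF is exactly the longest ORF of the realized sequence (TE insertions into
the ORF are recoded stop-free in frame first), and a noncoding transcript —
including derived AS isoforms, which splice in intron-derived sequence — is
re-drawn until it carries no stop-terminated ORF at or above the coding
floor. This is label consistency, not tuning: a "noncoding" transcript
containing a genuine long ORF would simply be mislabeled ground truth.

TE insertions are realized in transcript coordinates inside single exons
(so each corresponds to one contiguous genomic interval in the `.out`
file) as consensus fragments of 50–250 bp with 1% substitution noise;
transposase-family consensus sequences are themselves full ORFs and are
planted as entire gene ORFs. Intron insertions are recorded in the `.out`
but not in the exonic truth table — exonization requires exonic overlap.

What the generator does **not** emulate: sequencing error and alignment
uncertainty (identity/coverage are 1.0; the quality filter is exercised
with hand-built records), expression levels, compound AS events, TEs
spanning splice boundaries, nested/fragmented repeats, and genomic repeat
families diverged far from consensus. A green truth-recovery test
therefore establishes algorithmic correctness of each stage on clean
structures, not robustness to noisy alignments.

## Determinism and numerics

Every stochastic step flows from one `numpy` generator seeded by the
configuration; identical seeds give byte-identical output files, and the
pipeline's `summary.json` is byte-stable across reruns. Collapse and event
outputs are sorted on stable keys so results never depend on input order.
Proportion tests guard the degenerate pooled cases explicitly;
position-frequency matrices return zero frequencies (not NaN) for empty
columns; hexamer tables are finite everywhere by pseudocount.

## Known limitations

* The merge rule intentionally ignores 5′ ends entirely; two isoforms
  differing by a genuine alternative first-exon 5′ boundary (same intron
  chain) collapse together. Distinguishing degradation from alternative TSS
  needs external 5′-cap evidence, which is out of scope.
* COMPLEX regions are counted but not decomposed into nested simple
  events.
* The hexamer scorer's bootstrap training assumes the ORF-length rule is
  mostly right on the input; on heavily degraded transcript sets the
  bootstrap labels would be poor.
* Enrichment assumes the annotation universe is complete for the supplied
  gene sets; no correction for annotation bias is attempted.
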