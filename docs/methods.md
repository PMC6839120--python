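# Methods

## Coordinates and read geometry

All internal coordinates are 0-based, half-open; BED output is 0-based and
the TSV site tables report 1-based positions. A read's 3′ end (`end3`) is
its 3′-terminal *aligned* base: `aln_end − 1` on the forward strand,
`aln_start` on the reverse strand. Soft clips and mapped tails are stored in
read orientation (reverse-complemented for reverse alignments). Secondary
and supplementary alignments are dropped so each molecule contributes one 3′
end; unmapped reads are counted and skipped. Deletions and introns consume
reference in coverage (a read covers its whole aligned span); insertions do
not.

A cDNA read carries **poly(A) evidence** when its 3′ soft clip begins with
at least 10 As within its first 11 bases (one tolerated miscall). The
upstream tool chain that inspired this rule does not publish its exact
criterion, so both numbers are configuration keys
(`detection.polya_min_a`, `detection.polya_window`).

## Site detection

A position is a raw candidate when `ends3_polya ≥ 2` and
`ends3_polya / coverage ≥ 0.001` (same strand; zero coverage never yields a
candidate; both bounds inclusive). Window-maximum selection is greedy:
candidates are consumed in order of decreasing support and a candidate is
suppressed when an accepted site lies within 10 nt. Support ties break
toward the transcript-3′-most position (larger coordinate on `+`, smaller on
`−`) because cleavage heterogeneity biases real sites downstream; the greedy
result equals the per-cluster optimum (tested against brute force). The
"overlapping reads" denominator counts same-strand reads whose aligned
interval contains the position. A site is high-confidence when strictly more
than 10 poly(A)+ reads end in its 21-nt window.

## A-count

The A-count *n* walks the 20 nt strictly upstream of the site (the site base
is excluded), proximal base first and strand-aware: +1 per A, −1 per other
base (N counts as non-A, conservatively), halting when the counter *equals*
−1 or the window ends; the result is the running maximum (≥ 0). The halting
condition is taken literally as `== −1`; with ±1 steps a `< 0` reading is
identical, but the literal form is kept in case scores are ever changed. At
contig edges the walk simply runs shorter.

## TS classification

Sites with *n* < 3 are TESs outright — one A-rich notion (≥ 3 As) is used at
both site and read level. For A-rich sites, two rescue criteria:

1. **End-context majority.** Among all reads ending in the 21-nt window,
   more must end at non-A-rich positions than at A-rich ones. An end
   position is A-rich when a run of ≥ 3 As begins within the 3 nt
   immediately upstream (the geometry by which terminal tail As would have
   been absorbed into the alignment). The exact run-to-end geometry is not
   published; this rule is a design choice exposed via
   `classifier.read_arich_run`.
2. **Support fraction.** `window_support / overlap` must exceed
   `0.8 / (1 + 2^(−100(1/(20−n) − 0.08)))`. The fraction can exceed 1 (a
   site's window can collect ends from reads that stop just short of the
   site), which is harmless since the threshold is capped at 0.8. The
   *n* = 20 singularity is defined as the limit, 0.8. The threshold is
   strictly increasing over *n* = 0…19 (it saturates to 0.8 within double
   precision by *n* ≈ 19).

The opposite-strand override (≥ 100× more opposite-strand 5′ ends than
same-strand 3′ ends, inclusive) is evaluated over the 21-nt window rather
than a single base, for robustness to ±1 alignment wobble, and can demote a
TES call. Artifacts within 50 nt (inclusive, center-to-center, same strand)
of a TES are relabelled EXCLUDED and leave all comparisons, so TES-adjacent
PAS motifs and dRNA endings cannot contaminate the artifact class.
Multi-experiment merging matches sites within 10 nt on the same strand,
calls the merged locus TES if any experiment did, and places it at the
best-supported member's position (tie: 3′-most).

## Evaluation

dRNA confirmation: ≥ 0.5 % (inclusive) of overlapping same-strand dRNA reads
end in the 21-nt window; every dRNA ending counts because dRNA does not
sequence the terminal poly(A). PPV and NPV are left undefined (reported as
missing, never 0) when the kept or discarded set is empty. PolyA_DB-style
matching requires strand agreement — poly(A) sites are stranded — and
accepts BED or a column-mapped TSV dialect. A-count strata are reported per
integer value plus a merged "≥ 10" bin. Because a SQANTI-style discard
(≥ 17/20 As) implies an internal-priming discard (≥ 12/20), the IP filter's
kept set is contained in the SQANTI-style kept set on any genome; the
containment is asserted in tests.

## Tail measurement

The query is the last ≤ 30 mapped bases plus the first ≤ 150 soft-clipped
bases, capped at the 180-nt target length. Against a homopolymer target with
match +2 and mismatch = gap = −3, target-gaps cost exactly as much as
mismatches and query-gaps never help, so the Smith–Waterman optimum is
attained by a contiguous query segment; the implementation therefore scans
all substrings via prefix sums, which is provably score-identical to the
full recursion (verified against an independent full-DP aligner and
Biopython's `PairwiseAligner`). Among equal-scoring alignments the one with
the most query As wins, and the tail length is the number of query As inside
the winning alignment — mismatched bases within the segment are not counted.
The measure deliberately merges genomic As abutting the clip into the tail;
this overestimates tails at A-rich loci (internal-priming sites read ≈ 12 nt
high on the default fixture) but is robust to indel-rich tails. No
correction is attempted.

## PAS scanning

Twelve human hexamers, most-common-first (AATAAA, ATTAAA, TATAAA, AGTAAA,
AAGAAA, AATATA, AATACA, CATAAA, GATAAA, AATGAA, TTTAAA, ACTAAA), scanned
with exact matching over the 40 nt upstream window. Distance is measured
from the motif's 3′ end to the site (strand-aware, ≥ 1). The lowest-rank
motif wins; equal-rank hits resolve toward the expected 25-nt distance, then
the smaller distance, for determinism.

## The synthetic study

The generator's defaults are the conditions every end-to-end test and the
reproduction script run under: one 41.2-kb contig, 50 % GC, 80 loci 500 nt
apart with alternating strands — 40 genuine TESs (8 of which carry a genuine
upstream run of 6 As), 30 TS artifacts with target A-counts drawn from 3–5,
and 10 internal-priming artifacts with 12 upstream As. Per genuine TES: 100
poly(A)+ cDNA reads and 50 dRNA reads; per artifact: 20 poly(A)+ cDNA reads
inside a transcript body covered by 400 background cDNA and 200 background
dRNA reads (dRNA reads end only at genuine ends). Tail lengths are
N(50, 15) nt (clipped ≥ 5) for both TES and TS reads — one shared
distribution, so any measured median gap would indicate a measurement
artifact — and N(20, 2) for internal priming, the anchored-primer length.

Cleavage jitter at genuine TESs uses a discrete Laplace kernel,
P(k) ∝ exp(−|k|/scale) with scale 1 and |k| ≤ 6 (SD ≈ 1.3 nt): endings are
dispersed, as at real cleavage sites, while the modal position stays
identifiable at finite depth so detected positions are stable. (The config
field is named `tes_cleavage_scale` accordingly.) TS artifact reads all end
at exactly one position, emulating alignment collapse onto the A
homopolymer; mechanistically, the genomic A run (A-count + the site base)
absorbs the proximal part of the synthesized tail into the alignment and the
remainder is soft-clipped, so tail measurement should recover the drawn
length. Reads are error-free: the classifier consumes alignments, not
signal, and error-free fixtures keep the oracle checks sharp.

What the fixture does **not** emulate: sequencing errors and chimeras,
splicing, overlapping genes and antisense transcription, expression-level
heterogeneity, multi-contig genomes, and dRNA coverage bias. Passing tests
therefore demonstrate that the implementation realizes the stated decision
rules and recovers planted structure under clean conditions — not that the
filter achieves any particular accuracy on real libraries, where the
dRNA-based PPV/NPV are themselves estimates, not ground truth.

## Numerical and degenerate-input choices

- Detection, confirmation, fold-change and exclusion bounds are inclusive
  exactly as stated above; boundary behaviour is pinned by tests.
- Zero-coverage positions cannot become candidates; classifying a site with
  zero overlap is an error (it cannot arise from detection).
- Empty inputs produce empty tables and exit code 0; unknown contigs and
  unparseable records are data errors (exit code 2).
- All randomness flows from `numpy.random.default_rng(seed)`; the simulator
  derives sub-seeds (seed + 1 for cDNA, + 2 for dRNA) so regenerating any
  one artifact is deterministic.

## Known limitations

- Single-contig orientation of the pipeline helpers (the readers handle
  multi-record FASTA; orchestration processes the first/selected contig).
- The per-read A-rich end rule depends only on the end position, which is
  exact for the error-free fixture but a simplification for misaligned real
  reads.
- Tail overestimation at A-rich loci is documented, not corrected.
- The dRNA evaluation inherits the coverage-ratio caveat: with a high
  cDNA-to-dRNA depth ratio, PPV estimates sink and NPV estimates rise; the
  fixture's depths (100× vs 50×) keep both informative.
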