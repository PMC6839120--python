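# polyatrim

Template-switching-aware poly(A)-site calling and filtering for long-read
cDNA sequencing.

## The problem

Alternative polyadenylation is usually mapped from cDNA reads: a read whose
3′ soft clip is a poly(A) stretch marks a candidate cleavage site. cDNA is
prone to two artifact classes. *Internal priming* — the oligo-d(T) primer
annealing inside an A-rich stretch of the transcript — is routinely filtered
(discard sites with ≥ 6 consecutive or ≥ 12 of 20 upstream As). *Template
switching* (TS) — the reverse transcriptase jumping from the poly(A) tail
onto a genomic adenine stretch — produces spurious poly(A) sites at loci
with as few as 3–5 As, which internal-priming filters leave untouched.
`polyatrim` implements a classifier that targets TS specifically, and an
evaluation harness that scores it (and the conventional baselines) against
direct-RNA (dRNA) sequencing, which is free of reverse-transcription
artifacts.

## The method

1. **Detection.** A position is a candidate poly(A) site when ≥ 2 poly(A)+
   reads and ≥ 0.1 % of the same-strand overlapping reads end there; within
   any 21-nt window only the best-supported position survives. Sites with
   \> 10 window reads are flagged high-confidence.
2. **A-count.** The adenine content *n* of the 20 nt upstream of a site is
   scored by a halting counter: +1 per A, −1 per other base, stop at −1 or
   20 nt, report the running maximum. This weights As near the cleavage
   position without ignoring the broader window.
3. **TS classification.** Sites with *n* < 3 are transcriptional end sites
   (TES). An A-rich site is still a TES if its 21-nt window holds more reads
   ending at non-A-rich positions than at A-rich ones (a run of ≥ 3 As
   abutting the end), or if its support fraction exceeds the logistic
   threshold

   0.8 / (1 + 2^(−100·(1/(20−n) − 0.08))),

   which rises from ≈ 0.09 at *n* = 0 to 0.8 as *n* → 20. Loci with ≥ 100×
   more opposite-strand 5′ ends than 3′ ends are artifactual regardless, and
   artifacts within 50 nt of a TES are excluded from downstream comparisons.
   Multi-experiment runs are merged: a locus called TES in any experiment is
   a TES.
4. **Evaluation.** A site is dRNA-confirmed when ≥ 0.5 % of overlapping dRNA
   reads end in its 21-nt window (all dRNA endings count — dRNA does not
   sequence the terminal tail). PPV = confirmed fraction of kept sites,
   NPV = unconfirmed fraction of discarded sites, for the TS filter and the
   internal-priming, SQANTI-style (≥ 17/20 upstream As) and PolyA_DB-style
   (database hit within ± 10 nt) baselines.
5. **Sequence features.** PAS hexamer scan (12 canonical human motifs, 40 nt
   upstream, exact matches, most common wins, ties resolved toward the
   expected 25-nt distance); ± 50 nt nucleotide-composition profiles;
   per-site read-end heatmaps (± 10 nt); poly(A)-tail length by local
   alignment of the read 3′ terminus (last 30 mapped + first 150 clipped nt)
   against 180 As with scores +2 / −3 / −3 / −3, counting the query As in
   the best local alignment.

Everything is testable offline: `polyatrim.synth_fixtures` generates seeded
genomes, truth tables and cDNA/dRNA SAM files that plant genuine TESs
(dispersed cleavage, PAS at 25 nt, normal tails), TS artifacts (3–5 upstream
As, point-mass endings, the same tail distribution) and internal-priming
artifacts (12 upstream As, primer-length tails).

## Worked example

```sh
polyatrim simulate --seed 7 --out fixture/
polyatrim classify fixture/genome.fasta --experiment fixture/cdna.sam --out out/sites
polyatrim evaluate out/sites.tsv fixture/drna.sam fixture/genome.fasta --out out/eval
```

The classify step logs

```
INFO polyatrim: classified 80 sites: {'TS_ARTIFACT': 40, 'TES': 40}
```

— all 40 planted genuine sites kept, all 30 template-switching and 10
internal-priming artifacts discarded. `out/eval.evaluation.tsv` then reads

```
filter  ppv     npv     n_kept  n_discarded
TS      1.0000  1.0000  40      40
IP      0.5161  0.5556  62      18
SQANTI  0.5000          80      0
```

The TS filter's kept set is fully dRNA-confirmed and its discarded set fully
unconfirmed. The internal-priming baseline keeps all 30 low-A TS artifacts
(PPV 0.52) while discarding 8 genuine A-rich TESs (NPV 0.56), and the
SQANTI-style rule discards nothing at all on this fixture — the
qualitative ordering the filter is built to produce. Each command also
writes a `*.manifest.json` recording config, inputs and checksums, so
identical manifests reproduce outputs byte-identically.

## Layout

- `src/polyatrim/io_alignments.py` — FASTA/SAM input, strand-aware read-end
  extraction, end profiles, BED/TSV site tables
- `src/polyatrim/arich.py` — halting-counter A-count and classical measures
- `src/polyatrim/site_detection.py` — candidate detection and window maxima
- `src/polyatrim/ts_classifier.py` — TES/TS classification, overrides,
  exclusion, multi-experiment merging
- `src/polyatrim/validation.py` — dRNA confirmation, baselines, PPV/NPV
- `src/polyatrim/seq_features.py` — PAS, composition, heatmaps, tails
- `src/polyatrim/synth_fixtures.py` — seeded fixture generator
- `src/polyatrim/pipeline.py`, `src/polyatrim/cli.py` — orchestration and
  the `polyatrim` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
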