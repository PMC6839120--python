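"""Candidate poly(A)-site detection from poly(A)+ cDNA read 3' ends.

A genomic position is a raw candidate when at least ``min_reads`` poly(A)+
reads end exactly there and those endings make up at least ``min_frac`` of
the same-strand reads overlapping the position.  Within any 21-nt window only
the position with the most poly(A)+ endings is kept, so no two reported sites
on one strand are closer than 11 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import arich
from .config import DetectionConfig
from .io_alignments import STRANDS, EndProfile, GenomeSequence


@dataclass
class PolyASiteCandidate:
    """A candidate cleavage locus and its classification state."""

    contig: str
    pos: int
    strand: str
    support: int
    window_support: int = 0
    overlap: int = 0
    a_count: int = 0
    high_confidence: bool = False
    classification: str = "UNCLASSIFIED"
    source_experiment: str = ""
    pas: Optional[object] = None            # seq_features.PASHit
    drna_confirmed: Optional[bool] = None
    filter_verdicts: dict = field(default_factory=dict)

    def key(self) -> tuple[str, str, int]:
        return (self.contig, self.strand, self.pos)


def detect_candidates(
    profile: EndProfile, cfg: DetectionConfig | None = None
) -> list[PolyASiteCandidate]:
    """Scan the poly(A)-evidence end profile for raw candidate positions.

    Positions with zero overlapping reads never yield a candidate.
    """
    cfg = cfg or DetectionConfig()
    candidates: list[PolyASiteCandidate] = []
    for strand in STRANDS:
        ends = profile.ends3_polya[strand]
        cov = profile.coverage[strand]
        for pos in (ends >= cfg.min_reads).nonzero()[0]:
            pos = int(pos)
            if cov[pos] > 0 and ends[pos] / cov[pos] >= cfg.min_frac:
                candidates.append(PolyASiteCandidate(
                    contig=profile.contig, pos=pos, strand=strand,
                    support=int(ends[pos]),
                ))
    candidates.sort(key=lambda c: (c.strand, c.pos))
    return candidates


def select_window_maximum(
    candidates: list[PolyASiteCandidate], window: int = 21
) -> list[PolyASiteCandidate]:
    """Keep only the best-supported candidate of every ``window``-nt window.

    Greedy: candidates are taken in order of decreasing support (ties broken
    toward the transcript-3'-most position, i.e. the larger coordinate on the
    forward strand and the smaller on the reverse strand) and accepted unless
    an already-accepted same-strand site lies within half a window.
    """
    half = window // 2
    kept: list[PolyASiteCandidate] = []
    for strand in STRANDS:
        pool = [c for c in candidates if c.strand == strand]
        # tie-break: 3'-most first, i.e. descending pos on +, ascending on -
        pos_key = (lambda c: -c.pos) if strand == "+" else (lambda c: c.pos)
        pool.sort(key=lambda c: (-c.support, pos_key(c)))
        accepted_pos: list[int] = []
        for cand in pool:
            if all(abs(cand.pos - p) > half for p in accepted_pos):
                accepted_pos.append(cand.pos)
                kept.append(cand)
    kept.sort(key=lambda c: (c.strand, c.pos))
    return kept


def annotate_candidates(
    sites: list[PolyASiteCandidate],
    genome: GenomeSequence,
    profile: EndProfile,
    cfg: DetectionConfig | None = None,
) -> list[PolyASiteCandidate]:
    """Fill window support, overlap, A-count and the high-confidence flag."""
    cfg = cfg or DetectionConfig()
    for site in sites:
        site.window_support = profile.window_sum(
            profile.ends3_polya[site.strand], site.pos, cfg.window)
        site.overlap = int(profile.coverage[site.strand][site.pos])
        site.a_count = arich.a_count_upstream(genome, site.pos, site.strand)
        site.high_confidence = site.window_support > cfg.high_confidence_min
    return sites


def detect_sites(
    profile: EndProfile,
    genome: GenomeSequence,
    cfg: DetectionConfig | None = None,
) -> list[PolyASiteCandidate]:
    """Full detection: raw candidates, window maximum, annotation."""
    cfg = cfg or DetectionConfig()
    raw = detect_candidates(profile, cfg)
    kept = select_window_maximum(raw, cfg.window)
    return annotate_candidates(kept, genome, profile, cfg)
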