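"""Sequence features of called sites: PAS motifs, composition, tails.

Genuine cleavage sites carry a polyadenylation-signal hexamer (canonically
AATAAA) about 25 nt upstream, dispersed read endings, and soft-clipped
poly(A) tails; template-switching artifacts lack positioned signals and pile
their reads onto one nucleotide.  These functions quantify each contrast.

Poly(A)-tail length is measured by local alignment of the read's 3' terminus
(last 30 mapped nt plus the first 150 soft-clipped nt) against a stretch of
180 As with match +2, mismatch -3, gap open -3, gap extend -3; the number of
query As inside the best-scoring local alignment is the tail length.  With a
homopolymer target and gap cost equal to mismatch cost, the optimum is
attained by a contiguous query segment aligned without target gaps, so the
search reduces to an exhaustive best-substring scan that is score-identical
to the full Smith-Waterman recursion (ties between equal-scoring alignments
are resolved toward the higher A count).  Counting As this way is robust to
indel-rich nanopore tails but may overestimate tails abutting genomic A-rich
regions, since the mapped As merge with the clipped ones.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import FeaturesConfig
from .io_alignments import AlignedRead, EndProfile, GenomeSequence
from .site_detection import PolyASiteCandidate

BASES = "ACGT"


@dataclass(frozen=True)
class PASHit:
    """A polyadenylation-signal hexamer found upstream of a site."""

    motif: str
    distance: int  # nt from motif 3' end to the site, strand-aware, >= 1
    rank: int      # index in the configured most-common-first motif list


@dataclass(frozen=True)
class TailMeasurement:
    read_id: str
    tail_length: int
    sw_score: int


def find_pas(
    genome: GenomeSequence,
    site: PolyASiteCandidate,
    cfg: FeaturesConfig | None = None,
) -> Optional[PASHit]:
    """Best PAS hexamer in the strand-aware upstream window.

    Only exact matches count.  Among all hits the most common motif (lowest
    rank) wins; among equal-rank hits the one closest to the expected 25-nt
    distance wins (then the shorter distance, for determinism).
    """
    cfg = cfg or FeaturesConfig()
    # proximal-first upstream, reversed to transcript 5'->3' for matching
    upstream = genome.upstream(site.pos, site.strand, cfg.pas_upstream)[::-1]
    hits: list[PASHit] = []
    for rank, motif in enumerate(cfg.pas_motifs):
        start = 0
        while True:
            idx = upstream.find(motif, start)
            if idx == -1:
                break
            distance = len(upstream) - (idx + len(motif)) + 1
            hits.append(PASHit(motif=motif, distance=distance, rank=rank))
            start = idx + 1
    if not hits:
        return None
    return min(hits, key=lambda h: (
        h.rank, abs(h.distance - cfg.pas_expected_distance), h.distance))


def pas_distance_histogram(
    sites: Iterable[PolyASiteCandidate],
) -> dict[str, Counter]:
    """Per-class counts of PAS-to-site distances (sites without a hit skip)."""
    hist: dict[str, Counter] = defaultdict(Counter)
    for site in sites:
        if site.pas is not None:
            hist[site.classification][site.pas.distance] += 1
    return dict(hist)


def nucleotide_composition(
    sites: Iterable[PolyASiteCandidate],
    genome: GenomeSequence,
    cfg: FeaturesConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-class 4 x (2*flank+1) base-frequency matrices around sites.

    Columns run from -flank (upstream) to +flank in transcript orientation,
    column 0 being the site; each column with at least one observation sums
    to 1 over the four bases.  Windows truncated by contig ends are skipped.
    """
    cfg = cfg or FeaturesConfig()
    flank = cfg.composition_flank
    width = 2 * flank + 1
    counts: dict[str, np.ndarray] = defaultdict(
        lambda: np.zeros((4, width), dtype=np.int64))
    for site in sites:
        upstream = genome.upstream(site.pos, site.strand, flank)
        center_down = genome.downstream(site.pos, site.strand, flank + 1)
        if len(upstream) < flank or len(center_down) < flank + 1:
            continue
        window = upstream[::-1] + center_down  # 5'->3', site at index flank
        mat = counts[site.classification]
        for col, base in enumerate(window):
            if base in BASES:
                mat[BASES.index(base), col] += 1
    freqs: dict[str, np.ndarray] = {}
    for label, mat in counts.items():
        totals = mat.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[label] = np.where(totals > 0, mat / totals, 0.0)
    return freqs


def _best_a_segment(values: np.ndarray, is_a: np.ndarray) -> tuple[int, int]:
    """Maximum-sum contiguous segment; among ties, maximal A count.

    Exhaustive over all O(L^2) segments via prefix sums (L <= 180).
    Returns (score, a_count); the empty segment scores 0 with 0 As.
    """
    n = len(values)
    if n == 0:
        return 0, 0
    pv = np.concatenate(([0], np.cumsum(values)))
    pa = np.concatenate(([0], np.cumsum(is_a.astype(np.int64))))
    # scores[i, j] = sum over [i, j) for i < j
    scores = pv[None, 1:] - pv[:-1, None]
    acnts = pa[None, 1:] - pa[:-1, None]
    valid = np.tri(n, n, k=0, dtype=bool).T  # i <= j-1, i.e. nonempty i<j
    scores = np.where(valid, scores, np.iinfo(np.int64).min)
    best = int(scores.max())
    if best <= 0:
        return 0, 0
    tie = scores == best
    return best, int(acnts[tie].max())


def measure_tail(
    read: AlignedRead, cfg: FeaturesConfig | None = None
) -> TailMeasurement:
    """Poly(A)-tail length of one read by local alignment against poly(A).

    The query is the read's last <= 30 mapped bases followed by the first
    <= 150 soft-clipped bases (read orientation) and is capped at the target
    length; see the module docstring for the alignment reduction.
    """
    cfg = cfg or FeaturesConfig()
    query = (read.mapped_tail_seq[-cfg.tail_mapped_nt:]
             + read.clip3_seq[:cfg.tail_clip_nt])[:cfg.tail_target_nt]
    if not query:
        return TailMeasurement(read.read_id, 0, 0)
    arr = np.frombuffer(query.encode(), dtype=np.uint8)
    is_a = arr == ord("A")
    values = np.where(is_a, cfg.sw_match, cfg.sw_mismatch).astype(np.int64)
    score, a_count = _best_a_segment(values, is_a)
    return TailMeasurement(read.read_id, a_count, score)


def assign_reads_to_sites(
    reads: Iterable[AlignedRead],
    sites: Sequence[PolyASiteCandidate],
    window: int = 21,
) -> dict[tuple[str, str, int], list[AlignedRead]]:
    """Map poly(A)+ reads to the site whose 21-nt window holds their 3' end.

    A read matching several sites (impossible after window-maximum selection
    on one strand) would go to the nearest.
    """
    half = window // 2
    by_strand: dict[tuple[str, str], list[PolyASiteCandidate]] = defaultdict(list)
    for site in sites:
        by_strand[(site.contig, site.strand)].append(site)
    assignment: dict[tuple[str, str, int], list[AlignedRead]] = {
        s.key(): [] for s in sites}
    for read in reads:
        if not read.has_polyA_evidence:
            continue
        pool = by_strand.get((read.contig, read.strand), ())
        near = [s for s in pool if abs(s.pos - read.end3) <= half]
        if near:
            best = min(near, key=lambda s: abs(s.pos - read.end3))
            assignment[best.key()].append(read)
    return assignment


def tail_length_distribution(
    measurements: Mapping[str, TailMeasurement],
    assignment: Mapping[tuple[str, str, int], list[AlignedRead]],
    sites: Sequence[PolyASiteCandidate],
) -> dict[str, dict]:
    """Per-class tail-length arrays and medians.

    ``measurements`` is keyed by read id; reads without a measurement are
    skipped.  Classes with no reads are omitted.
    """
    per_class: dict[str, list[int]] = defaultdict(list)
    for site in sites:
        for read in assignment.get(site.key(), ()):
            m = measurements.get(read.read_id)
            if m is not None:
                per_class[site.classification].append(m.tail_length)
    out: dict[str, dict] = {}
    for label, lengths in per_class.items():
        arr = np.asarray(lengths)
        out[label] = {
            "lengths": arr,
            "median": float(np.median(arr)),
            "histogram": Counter(lengths),
        }
    return out


def end_position_heatmap(
    sites: Sequence[PolyASiteCandidate],
    profile: EndProfile,
    cfg: FeaturesConfig | None = None,
) -> dict[str, np.ndarray]:
    """Mean per-offset fraction of window read endings, per class.

    For every high-confidence site the poly(A)+ ending counts at offsets
    -flank..+flank (transcript orientation) are normalized to fractions and
    averaged within each classification.  Each returned row sums to 1.
    """
    cfg = cfg or FeaturesConfig()
    flank = cfg.heatmap_flank
    rows: dict[str, list[np.ndarray]] = defaultdict(list)
    for site in sites:
        if not site.high_confidence:
            continue
        lo, hi = site.pos - flank, site.pos + flank + 1
        if lo < 0 or hi > profile.length:
            continue
        window = profile.ends3_polya[site.strand][lo:hi].astype(float)
        if site.strand == "-":
            window = window[::-1]
        total = window.sum()
        if total > 0:
            rows[site.classification].append(window / total)
    return {label: np.mean(stack, axis=0) for label, stack in rows.items()}


def end_offset_dispersion(heatmap_row: np.ndarray) -> float:
    """Standard deviation (nt) of the mean end-offset profile."""
    flank = (len(heatmap_row) - 1) // 2
    offsets = np.arange(-flank, flank + 1)
    p = heatmap_row / heatmap_row.sum()
    mean = (p * offsets).sum()
    return float(np.sqrt((p * (offsets - mean) ** 2).sum()))
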