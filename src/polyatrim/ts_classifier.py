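"""Template-switching classification of candidate poly(A) sites.

A site whose upstream A-count ``n`` is below 3 is accepted as a
transcriptional end site (TES) outright.  A site at an A-rich locus is still
accepted if either

* more reads in its 21-nt window end at non-A-rich positions than at A-rich
  positions (template switching piles reads onto the A stretch itself), or
* its poly(A)+ support fraction exceeds a logistic threshold that rises with
  the A-count,

      cap / (1 + 2^(-rate * (1 / (20 - n) - offset)))

  with cap = 0.8, rate = 100, offset = 0.08 (the n = 20 singularity is the
  limit, 0.8).

Sites failing both criteria are template-switching artifacts.  A locus with
at least 100-fold more opposite-strand 5' ends than same-strand 3' ends in
its window is artifactual regardless (antisense-driven template switching),
and artifacts within 50 nt of a TES are excluded from downstream comparisons
so TES sequence features do not bleed into the artifact class.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .config import ClassifierConfig
from .io_alignments import AlignedRead, EndProfile, GenomeSequence
from .site_detection import PolyASiteCandidate

TES = "TES"
TS_ARTIFACT = "TS_ARTIFACT"
EXCLUDED = "EXCLUDED"


def logistic_threshold(n: int, cfg: ClassifierConfig | None = None) -> float:
    """Support-fraction threshold for a site with upstream A-count ``n``."""
    cfg = cfg or ClassifierConfig()
    if not 0 <= n <= 20:
        raise ValueError(f"A-count n={n} outside [0, 20]")
    if n == 20:
        return cfg.logistic_cap
    exponent = -cfg.logistic_rate * (1.0 / (20 - n) - cfg.logistic_offset)
    return cfg.logistic_cap / (1.0 + 2.0 ** exponent)


def end_position_is_arich(
    genome: GenomeSequence, pos: int, strand: str, cfg: ClassifierConfig | None = None
) -> bool:
    """Is a read 3' end at ``pos`` abutting a genomic A run?

    True iff a run of at least ``read_arich_run`` consecutive As begins
    within the strand-aware ``read_arich_run`` nt upstream of the end, i.e.
    the genomic As the terminal poly(A) could have aligned to touch the end.
    """
    cfg = cfg or ClassifierConfig()
    run = cfg.read_arich_run
    upstream = genome.upstream(pos, strand, run + run - 1)
    for start in range(run):
        segment = upstream[start:start + run]
        if len(segment) == run and set(segment) == {"A"}:
            return True
    return False


def read_end_is_arich(
    genome: GenomeSequence, read: AlignedRead, cfg: ClassifierConfig | None = None
) -> bool:
    """Per-read wrapper around :func:`end_position_is_arich`."""
    return end_position_is_arich(genome, read.end3, read.strand, cfg)


def classify_site(
    site: PolyASiteCandidate,
    genome: GenomeSequence,
    profile: EndProfile,
    cfg: ClassifierConfig | None = None,
) -> str:
    """TES-or-artifact call for one annotated site (no overrides applied)."""
    cfg = cfg or ClassifierConfig()
    if site.overlap == 0:
        raise ValueError(
            f"site {site.contig}:{site.pos}{site.strand} has zero overlap; "
            "detected sites always have coverage"
        )
    if site.a_count < cfg.arich_site_min:
        return TES
    half = cfg.window // 2
    lo = max(0, site.pos - half)
    hi = min(profile.length, site.pos + half + 1)
    ends = profile.ends3[site.strand]
    n_arich = n_non = 0
    for pos in range(lo, hi):
        count = int(ends[pos])
        if count == 0:
            continue
        if end_position_is_arich(genome, pos, site.strand, cfg):
            n_arich += count
        else:
            n_non += count
    if n_non > n_arich:
        return TES
    if site.window_support / site.overlap > logistic_threshold(site.a_count, cfg):
        return TES
    return TS_ARTIFACT


def opposite_strand_rule(
    site: PolyASiteCandidate,
    profile: EndProfile,
    cfg: ClassifierConfig | None = None,
) -> bool:
    """True (artifactual) iff opposite-strand 5' ends outnumber same-strand
    3' ends at least ``opposite_strand_fold``-fold over the 21-nt window."""
    cfg = cfg or ClassifierConfig()
    ends3 = profile.window_sum(profile.ends3[site.strand], site.pos, cfg.window)
    opp5 = profile.window_sum(
        profile.ends5[EndProfile.opposite(site.strand)], site.pos, cfg.window)
    return opp5 >= cfg.opposite_strand_fold * ends3


def classify_sites(
    sites: list[PolyASiteCandidate],
    genome: GenomeSequence,
    profile: EndProfile,
    cfg: ClassifierConfig | None = None,
    apply_exclusion: bool = True,
) -> list[PolyASiteCandidate]:
    """Classify every site, apply the opposite-strand override and, by
    default, the 50-nt exclusion."""
    cfg = cfg or ClassifierConfig()
    for site in sites:
        label = classify_site(site, genome, profile, cfg)
        if label == TES and opposite_strand_rule(site, profile, cfg):
            label = TS_ARTIFACT
        site.classification = label
    if apply_exclusion:
        exclude_near_tes(sites, cfg)
    return sites


def exclude_near_tes(
    sites: list[PolyASiteCandidate], cfg: ClassifierConfig | None = None
) -> list[PolyASiteCandidate]:
    """Relabel artifacts within ``exclusion_distance`` nt of a same-strand TES.

    Distances are center-to-center and the bound is inclusive; TES labels
    never change.
    """
    cfg = cfg or ClassifierConfig()
    tes_pos: dict[tuple[str, str], list[int]] = defaultdict(list)
    for site in sites:
        if site.classification == TES:
            tes_pos[(site.contig, site.strand)].append(site.pos)
    for site in sites:
        if site.classification != TS_ARTIFACT:
            continue
        if any(abs(site.pos - p) <= cfg.exclusion_distance
               for p in tes_pos[(site.contig, site.strand)]):
            site.classification = EXCLUDED
    return sites


def merge_experiment_calls(
    per_experiment_sites: Mapping[str, Iterable[PolyASiteCandidate]],
    cfg: ClassifierConfig | None = None,
) -> list[PolyASiteCandidate]:
    """Join per-experiment calls: a locus called TES anywhere is a TES.

    Sites from different experiments are matched when they fall within half a
    window (<= 10 nt) of one another on the same contig and strand; the
    merged site takes the position of the member with the greatest window
    support (tie: transcript-3'-most).
    """
    cfg = cfg or ClassifierConfig()
    half = cfg.window // 2
    pool: list[PolyASiteCandidate] = []
    for exp, sites in per_experiment_sites.items():
        for site in sites:
            if not site.source_experiment:
                site.source_experiment = exp
            pool.append(site)
    pool.sort(key=lambda s: (s.contig, s.strand, s.pos))

    merged: list[PolyASiteCandidate] = []
    cluster: list[PolyASiteCandidate] = []

    def flush() -> None:
        if not cluster:
            return
        three_most = (lambda s: s.pos) if cluster[0].strand == "+" else (lambda s: -s.pos)
        best = max(cluster, key=lambda s: (s.window_support, three_most(s)))
        if any(s.classification == TES for s in cluster):
            best.classification = TES
        best.source_experiment = ",".join(
            sorted({s.source_experiment for s in cluster}))
        merged.append(best)

    for site in pool:
        if cluster and (site.contig, site.strand) == (cluster[-1].contig, cluster[-1].strand) \
                and site.pos - cluster[-1].pos <= half:
            cluster.append(site)
        else:
            flush()
            cluster = [site]
    flush()
    merged.sort(key=lambda s: (s.contig, s.strand, s.pos))
    return merged
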