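"""dRNA-based confirmation, baseline filters and PPV/NPV evaluation.

Direct-RNA reads carry no reverse-transcription artifacts, so a candidate
poly(A) site is taken as confirmed when at least 0.5% of the overlapping
dRNA reads end within its 21-nt window (every dRNA read ending counts, since
dRNA does not sequence the terminal poly(A)).  Against that reference,
positive predictive value is the confirmed fraction of kept sites and
negative predictive value the unconfirmed fraction of discarded sites, for
the TS filter and for three baselines: the conventional internal-priming
filter (>= 6 consecutive or >= 12 of 20 upstream As), a SQANTI-style filter
(> 80%, i.e. >= 17 of 20 upstream As) and a PolyA_DB-style database lookup.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from . import arich
from .config import ValidationConfig
from .io_alignments import EndProfile, GenomeSequence
from .site_detection import PolyASiteCandidate
from .ts_classifier import EXCLUDED, TES

FILTER_NAMES = ("TS", "IP", "SQANTI", "POLYADB")


@dataclass(frozen=True)
class FilterVerdict:
    site_key: tuple[str, str, int]
    filter_name: str
    keep: bool


@dataclass
class EvaluationResult:
    """PPV/NPV of one filter, overall and stratified by A-count."""

    filter_name: str
    ppv: Optional[float]
    npv: Optional[float]
    n_kept: int
    n_discarded: int
    strata: dict = field(default_factory=dict)  # a_count bin -> (ppv, n_kept)


def drna_confirms(
    site: PolyASiteCandidate,
    drna_profile: EndProfile,
    cfg: ValidationConfig | None = None,
) -> bool:
    """Confirmation by dRNA endings: >= ``drna_min_frac`` of overlapping
    same-strand dRNA reads end in the 21-nt window.  Zero overlap → False."""
    cfg = cfg or ValidationConfig()
    overlap = int(drna_profile.coverage[site.strand][site.pos])
    if overlap == 0:
        return False
    window_ends = drna_profile.window_sum(
        drna_profile.ends3[site.strand], site.pos, cfg.window)
    return window_ends / overlap >= cfg.drna_min_frac


def internal_priming_filter(
    site: PolyASiteCandidate,
    genome: GenomeSequence,
    cfg: ValidationConfig | None = None,
) -> bool:
    """Conventional internal-priming rule; keep unless the upstream 20 nt
    hold a run of >= 6 As or >= 12 As in total."""
    cfg = cfg or ValidationConfig()
    assessment = arich.assess(genome, site.pos, site.strand)
    return not (assessment.max_consecutive_a >= cfg.ip_min_run
                or assessment.a_in_20 >= cfg.ip_min_a_in_20)


def sqanti_like_filter(
    site: PolyASiteCandidate,
    genome: GenomeSequence,
    cfg: ValidationConfig | None = None,
) -> bool:
    """SQANTI-style rule; keep unless > 80% of the upstream 20 nt are As
    (17 of 20 is the smallest integer count above 80%)."""
    cfg = cfg or ValidationConfig()
    return arich.a_in_20(genome, site.pos, site.strand) < cfg.sqanti_min_a_in_20


def polyadb_like_filter(
    site: PolyASiteCandidate,
    db_sites: Iterable[tuple[str, int, str]],
    cfg: ValidationConfig | None = None,
) -> bool:
    """Keep iff a database site on the same contig and strand lies within the
    site's 21-nt window (pos +/- 10, inclusive)."""
    cfg = cfg or ValidationConfig()
    half = cfg.polyadb_window // 2
    return any(contig == site.contig and strand == site.strand
               and abs(pos - site.pos) <= half
               for contig, pos, strand in db_sites)


def load_polyadb(
    path: str | Path,
    columns: tuple[int, int, int] = (0, 1, 5),
    one_based: bool = False,
) -> list[tuple[str, int, str]]:
    """Read a poly(A)-site database as BED (default) or a TSV dialect.

    ``columns`` maps (chrom, position, strand) to 0-based column indices;
    set ``one_based`` for databases reporting 1-based positions.
    """
    records: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig = parts[columns[0]]
            pos = int(parts[columns[1]]) - (1 if one_based else 0)
            strand = parts[columns[2]]
            records.append((contig, pos, strand))
    return records


def evaluate_filter(
    sites: Sequence[PolyASiteCandidate],
    keep: Mapping[tuple[str, str, int], bool],
    confirmed: Mapping[tuple[str, str, int], bool],
    filter_name: str,
    high_confidence_only: bool = False,
) -> EvaluationResult:
    """PPV/NPV of one filter against dRNA confirmation.

    EXCLUDED sites are omitted; an empty kept (or discarded) set leaves PPV
    (or NPV) undefined rather than zero.  Strata report per-A-count PPV plus
    a merged ">=10" bin.
    """
    pool = [s for s in sites if s.classification != EXCLUDED]
    if high_confidence_only:
        pool = [s for s in pool if s.high_confidence]
    kept = [s for s in pool if keep[s.key()]]
    discarded = [s for s in pool if not keep[s.key()]]
    ppv = (sum(confirmed[s.key()] for s in kept) / len(kept)) if kept else None
    npv = (sum(not confirmed[s.key()] for s in discarded) / len(discarded)
           ) if discarded else None

    strata: dict = {}
    bins: dict = {}
    for s in kept:
        bins.setdefault(s.a_count, []).append(confirmed[s.key()])
        if s.a_count >= 10:
            bins.setdefault("10+", []).append(confirmed[s.key()])
    for key, values in sorted(bins.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])):
        strata[key] = (sum(values) / len(values), len(values))

    return EvaluationResult(
        filter_name=filter_name, ppv=ppv, npv=npv,
        n_kept=len(kept), n_discarded=len(discarded), strata=strata,
    )


def run_all_filters(
    sites: Sequence[PolyASiteCandidate],
    genome: GenomeSequence,
    drna_profile: EndProfile,
    polyadb: Optional[Iterable[tuple[str, int, str]]] = None,
    cfg: ValidationConfig | None = None,
) -> tuple[dict[str, dict], dict]:
    """Apply the TS call and all baselines; return per-filter keep maps and
    the dRNA confirmation map.  The TS filter keeps sites classified TES."""
    cfg = cfg or ValidationConfig()
    keep_maps: dict[str, dict] = {name: {} for name in FILTER_NAMES}
    confirmed: dict = {}
    db = list(polyadb) if polyadb is not None else None
    for site in sites:
        key = site.key()
        confirmed[key] = drna_confirms(site, drna_profile, cfg)
        site.drna_confirmed = confirmed[key]
        keep_maps["TS"][key] = site.classification == TES
        keep_maps["IP"][key] = internal_priming_filter(site, genome, cfg)
        keep_maps["SQANTI"][key] = sqanti_like_filter(site, genome, cfg)
        if db is not None:
            keep_maps["POLYADB"][key] = polyadb_like_filter(site, db, cfg)
        site.filter_verdicts = {
            name: keep_maps[name].get(key) for name in FILTER_NAMES
            if key in keep_maps[name]
        }
    if db is None:
        del keep_maps["POLYADB"]
    return keep_maps, confirmed


def evaluation_callable(  # small helper for symmetric CLI/table output
    results: Iterable[EvaluationResult],
) -> list[dict]:
    rows = []
    for res in results:
        rows.append({
            "filter": res.filter_name,
            "ppv": "" if res.ppv is None else f"{res.ppv:.4f}",
            "npv": "" if res.npv is None else f"{res.npv:.4f}",
            "n_kept": res.n_kept,
            "n_discarded": res.n_discarded,
        })
    return rows


def write_evaluation(results: Iterable[EvaluationResult], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["filter", "ppv", "npv", "n_kept", "n_discarded"],
            delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in evaluation_callable(results):
            writer.writerow(row)
    return path
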