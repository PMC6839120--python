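"""Genome/alignment input, strand-aware read-end extraction and site tables.

Coordinates are 0-based, half-open everywhere inside the package; BED output
is 0-based and the TSV site table reports 1-based positions for human
readability.  The read 3' end (``end3``) is the genomic coordinate of the
3'-terminal *aligned* base: ``aln_end - 1`` on the forward strand and
``aln_start`` on the reverse strand.  Soft-clip and tail sequences are kept
in read orientation (reverse-complemented for reverse-strand alignments) so
downstream code never has to re-orient them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .config import DetectionConfig

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig as an uppercase A/C/G/T/N string."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for contig {self.contig_name!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_name!r} contains non-IUPAC characters "
                f"beyond N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        if not 0 <= pos < len(self.sequence):
            raise IndexError(
                f"position {pos} outside contig {self.contig_name!r} "
                f"[0, {len(self.sequence)})"
            )
        return self.sequence[pos]

    def upstream(self, pos: int, strand: str, length: int) -> str:
        """Strand-aware upstream sequence, proximal base first.

        The returned string starts at the base adjacent to ``pos`` on the
        transcript-5' side and moves away from the site; on the reverse
        strand bases are complemented so the string reads in transcript
        sense.  Truncated at contig boundaries.
        """
        if strand == "+":
            start = max(0, pos - length)
            return self.sequence[start:pos][::-1]
        if strand == "-":
            end = min(len(self.sequence), pos + 1 + length)
            return self.sequence[pos + 1:end].translate(_COMPLEMENT)
        raise ValueError(f"invalid strand {strand!r}")

    def downstream(self, pos: int, strand: str, length: int) -> str:
        """Strand-aware sequence starting at ``pos`` itself, transcript sense."""
        if strand == "+":
            end = min(len(self.sequence), pos + length)
            return self.sequence[pos:end]
        if strand == "-":
            start = max(0, pos - length + 1)
            return self.sequence[start:pos + 1].translate(_COMPLEMENT)[::-1]
        raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read with strand-aware 3'-end geometry."""

    read_id: str
    contig: str
    strand: str
    aln_start: int
    aln_end: int
    end3: int
    end5: int
    clip3_seq: str
    mapped_tail_seq: str
    has_polyA_evidence: bool

    def __post_init__(self) -> None:
        if not self.aln_start < self.aln_end:
            raise ValueError("aln_start must be < aln_end")
        for coord in (self.end3, self.end5):
            if not self.aln_start <= coord < self.aln_end:
                raise ValueError("read ends must lie inside the aligned interval")


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a FASTA file into ``{contig_name: GenomeSequence}``.

    Sequences are uppercased and U is normalized to T; record order is
    preserved (dicts keep insertion order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    genomes: dict[str, GenomeSequence] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        genomes[name] = GenomeSequence(name, seq)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line)
    flush()
    if not genomes:
        raise ValueError(f"{path}: no FASTA records")
    return genomes


def has_polya_clip(clip3_seq: str, min_a: int = 10, window: int = 11) -> bool:
    """Poly(A)-evidence rule for a 3' soft clip.

    True iff the clip begins with at least ``min_a`` adenines within its
    first ``window`` bases (default: >= 10 As allowing <= 1 non-A among the
    first 11 positions).
    """
    head = clip3_seq[:window]
    return head.count("A") >= min_a


def load_reads(
    path: str | Path,
    genome: Mapping[str, GenomeSequence],
    detection: DetectionConfig | None = None,
    counters: dict[str, int] | None = None,
) -> list[AlignedRead]:
    """Read a BAM/SAM file into :class:`AlignedRead` records.

    Secondary and supplementary alignments are ignored (one 3' end per
    molecule); unmapped reads are skipped and counted in ``counters``.
    """
    detection = detection or DetectionConfig()
    reads: list[AlignedRead] = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.is_secondary:
                skipped["secondary"] += 1
                continue
            if aln.is_supplementary:
                skipped["supplementary"] += 1
                continue
            contig = aln.reference_name
            if contig not in genome:
                raise ValueError(
                    f"alignment {aln.query_name!r} refers to unknown contig "
                    f"{contig!r}; known: {sorted(genome)}"
                )
            if not any(op in (0, 7, 8) for op, _ in (aln.cigartuples or [])):
                raise ValueError(
                    f"read {aln.query_name!r}: CIGAR has no alignment-consuming ops"
                )
            reads.append(_to_aligned_read(aln, detection))
    if counters is not None:
        counters.update(skipped)
    return reads


def _to_aligned_read(aln: pysam.AlignedSegment, detection: DetectionConfig) -> AlignedRead:
    strand = "-" if aln.is_reverse else "+"
    start, end = aln.reference_start, aln.reference_end
    qseq = aln.query_sequence or ""
    qstart, qend = aln.query_alignment_start, aln.query_alignment_end
    if strand == "+":
        end3, end5 = end - 1, start
        clip3 = qseq[qend:]
        mapped_tail = qseq[max(qstart, qend - 30):qend]
    else:
        end3, end5 = start, end - 1
        # read orientation: reverse-complement; the 3' clip is the left clip
        clip3 = reverse_complement(qseq[:qstart])
        mapped_tail = reverse_complement(qseq[qstart:min(qend, qstart + 30)])
    return AlignedRead(
        read_id=aln.query_name,
        contig=aln.reference_name,
        strand=strand,
        aln_start=start,
        aln_end=end,
        end3=end3,
        end5=end5,
        clip3_seq=clip3.upper(),
        mapped_tail_seq=mapped_tail.upper(),
        has_polyA_evidence=has_polya_clip(
            clip3.upper(), detection.polya_min_a, detection.polya_window
        ),
    )


@dataclass
class EndProfile:
    """Per-contig, per-strand read-end and coverage arrays.

    ``ends3`` counts every read 3' end; ``ends3_polya`` restricts to reads
    with poly(A) evidence (the view candidate detection uses, identical to
    ``ends3`` for dRNA inputs where no clip is polyadenylated).  ``coverage``
    counts same-strand reads whose aligned interval contains the position
    (deletions/introns consume reference).
    """

    contig: str
    length: int
    ends3: dict[str, np.ndarray] = field(default_factory=dict)
    ends3_polya: dict[str, np.ndarray] = field(default_factory=dict)
    ends5: dict[str, np.ndarray] = field(default_factory=dict)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)

    def window_sum(self, array: np.ndarray, pos: int, window: int) -> int:
        half = window // 2
        lo, hi = max(0, pos - half), min(self.length, pos + half + 1)
        return int(array[lo:hi].sum())

    @staticmethod
    def opposite(strand: str) -> str:
        return "-" if strand == "+" else "+"


def build_end_profile(
    reads: Iterable[AlignedRead], contig: str, length: int
) -> EndProfile:
    """Accumulate 3'/5' end counts and coverage for one contig."""
    profile = EndProfile(contig=contig, length=length)
    for s in STRANDS:
        profile.ends3[s] = np.zeros(length, dtype=np.int64)
        profile.ends3_polya[s] = np.zeros(length, dtype=np.int64)
        profile.ends5[s] = np.zeros(length, dtype=np.int64)
        profile.coverage[s] = np.zeros(length, dtype=np.int64)
    cov_diff = {s: np.zeros(length + 1, dtype=np.int64) for s in STRANDS}
    for read in reads:
        if read.contig != contig:
            raise ValueError(f"read {read.read_id!r} not on contig {contig!r}")
        s = read.strand
        profile.ends3[s][read.end3] += 1
        if read.has_polyA_evidence:
            profile.ends3_polya[s][read.end3] += 1
        profile.ends5[s][read.end5] += 1
        cov_diff[s][read.aln_start] += 1
        cov_diff[s][read.aln_end] -= 1
    for s in STRANDS:
        profile.coverage[s] = np.cumsum(cov_diff[s][:-1])
    return profile


_TSV_COLUMNS = (
    "contig", "pos_1based", "strand", "support", "window_support", "overlap",
    "a_count", "high_confidence", "classification", "pas_motif",
    "pas_distance", "drna_confirmed", "source_experiment",
)


def write_sites(sites: Sequence, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write classified sites as ``<prefix>.bed`` (BED6) and ``<prefix>.tsv``.

    The BED name field carries the classification; the BED score is the
    window support (capped at 1000 per BED convention).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    with open(bed_path, "w") as bed:
        for s in sites:
            score = min(int(s.window_support), 1000)
            bed.write(
                f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.classification}\t"
                f"{score}\t{s.strand}\n"
            )
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for s in sites:
            pas = getattr(s, "pas", None)
            writer.writerow([
                s.contig, s.pos + 1, s.strand, s.support, s.window_support,
                s.overlap, s.a_count, int(s.high_confidence), s.classification,
                pas.motif if pas else ".",
                pas.distance if pas else ".",
                "." if s.drna_confirmed is None else int(s.drna_confirmed),
                s.source_experiment or ".",
            ])
    return bed_path, tsv_path


def read_sites(tsv_path: str | Path) -> list:
    """Read back a TSV site table written by :func:`write_sites`."""
    from .seq_features import PASHit
    from .site_detection import PolyASiteCandidate

    sites = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pas = None
            if row["pas_motif"] != ".":
                pas = PASHit(motif=row["pas_motif"],
                             distance=int(row["pas_distance"]), rank=-1)
            sites.append(PolyASiteCandidate(
                contig=row["contig"],
                pos=int(row["pos_1based"]) - 1,
                strand=row["strand"],
                support=int(row["support"]),
                window_support=int(row["window_support"]),
                overlap=int(row["overlap"]),
                a_count=int(row["a_count"]),
                high_confidence=bool(int(row["high_confidence"])),
                classification=row["classification"],
                pas=pas,
                drna_confirmed=(None if row["drna_confirmed"] == "."
                                else bool(int(row["drna_confirmed"]))),
                source_experiment=("" if row["source_experiment"] == "."
                                   else row["source_experiment"]),
            ))
    return sites


def mirror_genome(genome: GenomeSequence) -> GenomeSequence:
    """Reverse-complement a contig (strand-symmetry testing helper)."""
    return GenomeSequence(genome.contig_name, reverse_complement(genome.sequence))


def mirror_read(read: AlignedRead, length: int) -> AlignedRead:
    """Map a read onto the reverse-complemented contig of given length.

    Read-orientation fields (clips, tails, evidence) are invariant; only the
    genomic geometry flips.
    """
    return replace(
        read,
        strand=EndProfile.opposite(read.strand),
        aln_start=length - read.aln_end,
        aln_end=length - read.aln_start,
        end3=length - 1 - read.end3,
        end5=length - 1 - read.end5,
    )
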