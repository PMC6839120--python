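"""Seeded synthetic genomes and cDNA/dRNA alignments with known truth.

The generator plants three locus classes on a random genome, alternating
strands so both code paths stay exercised:

* **Genuine TESs** — a PAS hexamer (AATAAA) ends exactly 25 nt upstream,
  cleavage positions disperse around the modal site (discrete Laplace
  kernel), and reads carry soft-clipped poly(A) tails drawn from one shared
  normal distribution.  A configurable subset has a genuine A-rich upstream
  run (6 As), the class the conventional internal-priming filter wrongly
  discards.
* **Template-switching artifacts** — the upstream region holds only 3-5 As
  (the run ends at the site base).  Every artifact read ends at exactly one
  position because the aligner absorbs the proximal tail As into the genomic
  A run; the soft clip keeps the remainder, so the drawn tail length is what
  tail measurement should recover.  Artifact loci sit inside covered
  transcript bodies: deep non-poly(A) cDNA background and dRNA background
  span them, but no dRNA read ends there.
* **Internal-priming artifacts** — 12 As in the upstream 20 nt and
  primer-length (about 20 nt) tails.

dRNA reads end only at genuine TESs (plus-minus 2 nt) and carry no poly(A)
soft clip, emulating that dRNA does not sequence the terminal tail.

All outputs (FASTA, SAM, truth BED/TSV) are deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .config import SimulationConfig
from .io_alignments import GenomeSequence, reverse_complement

TES = "TES"
TS_ARTIFACT = "TS_ARTIFACT"
IP_ARTIFACT = "IP_ARTIFACT"

_NON_A = "CGT"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted locus."""

    contig: str
    pos: int
    strand: str
    kind: str  # TES, TS_ARTIFACT or IP_ARTIFACT
    planted_a_count: int
    planted_pas: Optional[tuple[str, int]]  # (motif, distance) or None


def _laplace_offsets(rng: np.random.Generator, n: int, scale: float,
                     bound: int = 6) -> np.ndarray:
    """Discrete Laplace cleavage jitter: P(k) proportional to exp(-|k|/scale)."""
    ks = np.arange(-bound, bound + 1)
    w = np.exp(-np.abs(ks) / scale)
    return rng.choice(ks, size=n, p=w / w.sum())


class _GenomeEditor:
    """Writes transcript-sense bases around a site onto the genome array."""

    def __init__(self, seq: np.ndarray):
        self.seq = seq

    def set_upstream(self, pos: int, strand: str, offset: int, bases: str) -> None:
        """Write ``bases`` (transcript sense, proximal-first) at upstream
        offsets ``offset``, ``offset+1``, ..."""
        for i, base in enumerate(bases):
            off = offset + i
            if strand == "+":
                self.seq[pos - off] = base
            else:
                self.seq[pos + off] = reverse_complement(base)

    def set_site_and_downstream(self, pos: int, strand: str, bases: str) -> None:
        """Write ``bases`` (transcript sense) at offsets 0, 1, ... downstream."""
        for i, base in enumerate(bases):
            if strand == "+":
                self.seq[pos + i] = base
            else:
                self.seq[pos - i] = reverse_complement(base)


def _fill(rng: np.random.Generator, n: int) -> str:
    """Random A-free filler."""
    return "".join(rng.choice(list(_NON_A), size=n))


def generate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[TruthRecord]]:
    """Random genome with engineered loci and the matching truth records."""
    rng = rng or np.random.default_rng(cfg.seed)
    length = cfg.resolved_genome_length()
    p_gc = cfg.gc_content / 2
    p_at = (1 - cfg.gc_content) / 2
    seq = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])

    kinds = ([TES] * (cfg.n_tes - cfg.n_arich_tes)
             + ["ARICH_TES"] * cfg.n_arich_tes
             + [TS_ARTIFACT] * cfg.n_ts_artifacts
             + [IP_ARTIFACT] * cfg.n_ip_artifacts)
    rng.shuffle(kinds)

    editor = _GenomeEditor(seq)
    truth: list[TruthRecord] = []
    lo, hi = cfg.artifact_acount_range
    for i, kind in enumerate(kinds):
        pos = 600 + i * cfg.locus_spacing
        strand = "+" if i % 2 == 0 else "-"
        # site base and transcript-sense downstream: A-free so runs never
        # extend past the site (the TS branch overwrites the site base)
        editor.set_site_and_downstream(pos, strand, _fill(rng, 16))
        if kind in (TES, "ARICH_TES"):
            run = cfg.arich_tes_run if kind == "ARICH_TES" else 0
            upstream20 = "A" * run + _fill(rng, 20 - run)
            editor.set_upstream(pos, strand, 1, upstream20)
            editor.set_upstream(pos, strand, 21, _fill(rng, 4))
            # PAS with its 3' end exactly pas_distance nt upstream;
            # proximal-first writing reverses the motif
            editor.set_upstream(pos, strand, cfg.pas_distance, "AATAAA"[::-1])
            truth.append(TruthRecord(cfg.contig, pos, strand, TES, run,
                                     ("AATAAA", cfg.pas_distance)))
        elif kind == TS_ARTIFACT:
            k = int(rng.integers(lo, hi + 1))
            editor.set_upstream(pos, strand, 1, "A" * k + _fill(rng, 20 - k))
            editor.set_site_and_downstream(pos, strand, "A")  # run ends at site
            truth.append(TruthRecord(cfg.contig, pos, strand, TS_ARTIFACT, k, None))
        else:  # internal priming
            k = cfg.ip_upstream_a
            editor.set_upstream(pos, strand, 1, "A" * k + _fill(rng, 20 - k))
            truth.append(TruthRecord(cfg.contig, pos, strand, IP_ARTIFACT, k, None))
    genome = GenomeSequence(cfg.contig, "".join(seq))
    return genome, truth


@dataclass
class _SimRead:
    name: str
    strand: str
    aln_start: int
    aln_end: int   # half-open; end3 = aln_end-1 on +, aln_start on -
    clip3: str     # read-orientation 3' soft clip

    def to_sam(self, contig: str, genome: str) -> str:
        ref = genome[self.aln_start:self.aln_end]
        m = len(ref)
        if self.strand == "+":
            seq = ref + self.clip3
            cigar = f"{m}M{len(self.clip3)}S" if self.clip3 else f"{m}M"
            flag = 0
        else:
            seq = reverse_complement(self.clip3) + ref
            cigar = f"{len(self.clip3)}S{m}M" if self.clip3 else f"{m}M"
            flag = 16
        return (f"{self.name}\t{flag}\t{contig}\t{self.aln_start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{seq}\t*")


def _polya_read(name: str, strand: str, end3: int, body: int, tail: int) -> _SimRead:
    if strand == "+":
        return _SimRead(name, strand, end3 - body + 1, end3 + 1, "A" * tail)
    return _SimRead(name, strand, end3, end3 + body, "A" * tail)


def _span_read(name: str, strand: str, lo: int, hi: int) -> _SimRead:
    return _SimRead(name, strand, lo, hi, "")


def _write_sam(reads: list[_SimRead], genome: GenomeSequence, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    reads = sorted(reads, key=lambda r: (r.aln_start, r.name))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{genome.contig_name}\tLN:{len(genome)}\n")
        for read in reads:
            fh.write(read.to_sam(genome.contig_name, genome.sequence) + "\n")


def _draw_tail(rng: np.random.Generator, n: int, mean: float, sd: float,
               minimum: int) -> np.ndarray:
    return np.maximum(np.rint(rng.normal(mean, sd, size=n)), minimum).astype(int)


def simulate_cdna(
    cfg: SimulationConfig,
    truth: list[TruthRecord],
    genome: GenomeSequence,
    out_sam: str | Path,
    rng: np.random.Generator | None = None,
    experiment: str = "cdna",
) -> Path:
    """Emit a cDNA SAM embodying the per-class end/tail contrasts."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    reads: list[_SimRead] = []
    length = len(genome)
    for li, rec in enumerate(truth):
        prefix = f"{experiment}_L{li}"
        sign = 1 if rec.strand == "+" else -1
        if rec.kind == TES:
            n = cfg.cdna_depth
            offsets = _laplace_offsets(rng, n, cfg.tes_cleavage_scale)
            tails = _draw_tail(rng, n, cfg.tail_mean, cfg.tail_sd, cfg.tail_min)
            bodies = rng.integers(150, 300, size=n)
            for j in range(n):
                end3 = rec.pos + sign * int(offsets[j])
                reads.append(_polya_read(f"{prefix}_p{j}", rec.strand, end3,
                                         int(bodies[j]), int(tails[j])))
            n_bg = cfg.tes_background
        else:
            n = cfg.artifact_support
            if rec.kind == TS_ARTIFACT:
                # aligner absorbs the genomic A run (a_count upstream As plus
                # the site base) out of the drawn tail; remainder is clipped
                absorbed = rec.planted_a_count + 1
                tails = _draw_tail(rng, n, cfg.tail_mean, cfg.tail_sd, cfg.tail_min)
                clips = np.maximum(tails - absorbed, 0)
            else:
                clips = _draw_tail(rng, n, cfg.ip_tail_len, cfg.ip_tail_sd,
                                   cfg.tail_min)
            bodies = rng.integers(150, 300, size=n)
            for j in range(n):
                reads.append(_polya_read(f"{prefix}_p{j}", rec.strand, rec.pos,
                                         int(bodies[j]), int(clips[j])))
            n_bg = cfg.artifact_background
        # non-poly(A) background spanning the locus, 3' ends far from windows
        for j in range(n_bg):
            jitter = int(rng.integers(0, 30))
            if rec.strand == "+":
                lo = max(0, rec.pos - 200 - jitter)
                hi = min(length, rec.pos + 120 + jitter)
            else:
                lo = max(0, rec.pos - 120 - jitter)
                hi = min(length, rec.pos + 200 + jitter)
            reads.append(_span_read(f"{prefix}_b{j}", rec.strand, lo, hi))
    out = Path(out_sam)
    _write_sam(reads, genome, out)
    return out


def simulate_drna(
    cfg: SimulationConfig,
    truth: list[TruthRecord],
    genome: GenomeSequence,
    out_sam: str | Path,
    rng: np.random.Generator | None = None,
) -> Path:
    """Emit a dRNA SAM: endings at genuine TESs only, no poly(A) clips."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    reads: list[_SimRead] = []
    length = len(genome)
    for li, rec in enumerate(truth):
        prefix = f"drna_L{li}"
        sign = 1 if rec.strand == "+" else -1
        if rec.kind == TES:
            for j in range(cfg.drna_depth):
                end3 = rec.pos + sign * int(rng.integers(-2, 3))
                body = int(rng.integers(120, 260))
                if rec.strand == "+":
                    reads.append(_span_read(f"{prefix}_d{j}", "+",
                                            end3 - body + 1, end3 + 1))
                else:
                    reads.append(_span_read(f"{prefix}_d{j}", "-",
                                            end3, end3 + body))
        else:
            # transcript-body coverage reading through the artifact locus
            for j in range(cfg.drna_background):
                jitter = int(rng.integers(0, 30))
                if rec.strand == "+":
                    lo = max(0, rec.pos - 200 - jitter)
                    hi = min(length, rec.pos + 120 + jitter)
                else:
                    lo = max(0, rec.pos - 120 - jitter)
                    hi = min(length, rec.pos + 200 + jitter)
                reads.append(_span_read(f"{prefix}_d{j}", rec.strand, lo, hi))
    out = Path(out_sam)
    _write_sam(reads, genome, out)
    return out


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f">{genome.contig_name}\n")
        for i in range(0, len(genome), width):
            fh.write(genome.sequence[i:i + width] + "\n")
    return path


def write_truth(truth: list[TruthRecord], path_prefix: str | Path) -> tuple[Path, Path]:
    """Serialize truth as ``<prefix>.bed`` (0-based) and ``<prefix>.tsv``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    with open(bed_path, "w") as bed:
        for rec in truth:
            bed.write(f"{rec.contig}\t{rec.pos}\t{rec.pos + 1}\t{rec.kind}\t"
                      f"{rec.planted_a_count}\t{rec.strand}\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["contig", "pos", "strand", "kind", "planted_a_count",
                         "pas_motif", "pas_distance"])
        for rec in truth:
            motif, dist = rec.planted_pas if rec.planted_pas else (".", ".")
            writer.writerow([rec.contig, rec.pos, rec.strand, rec.kind,
                             rec.planted_a_count, motif, dist])
    return bed_path, tsv_path


def read_truth(tsv_path: str | Path) -> list[TruthRecord]:
    truth: list[TruthRecord] = []
    with open(tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pas = None
            if row["pas_motif"] != ".":
                pas = (row["pas_motif"], int(row["pas_distance"]))
            truth.append(TruthRecord(
                contig=row["contig"], pos=int(row["pos"]), strand=row["strand"],
                kind=row["kind"], planted_a_count=int(row["planted_a_count"]),
                planted_pas=pas))
    return truth


def generate_bundle(
    cfg: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Genome, truth, cDNA and dRNA SAMs in one seeded call."""
    out = Path(out_dir)
    rng = np.random.default_rng(cfg.seed)
    genome, truth = generate_genome(cfg, rng)
    paths = {
        "genome": write_genome_fasta(genome, out / "genome.fasta"),
        "cdna": simulate_cdna(cfg, truth, genome, out / "cdna.sam",
                              np.random.default_rng(cfg.seed + 1)),
        "drna": simulate_drna(cfg, truth, genome, out / "drna.sam",
                              np.random.default_rng(cfg.seed + 2)),
    }
    truth_bed, truth_tsv = write_truth(truth, out / "truth")
    paths["truth_bed"] = truth_bed
    paths["truth_tsv"] = truth_tsv
    return paths
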