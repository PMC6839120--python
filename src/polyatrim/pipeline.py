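"""End-to-end orchestration: detection, classification, evaluation, features.

Thin composition layer over the individual modules, shared by the CLI, the
test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import seq_features, synth_fixtures, validation
from .config import PipelineConfig
from .io_alignments import (
    AlignedRead,
    EndProfile,
    GenomeSequence,
    build_end_profile,
    load_genome,
    load_reads,
)
from .site_detection import PolyASiteCandidate, detect_sites
from .ts_classifier import classify_sites, merge_experiment_calls
from .validation import EvaluationResult, evaluate_filter, run_all_filters


@dataclass
class StudyResult:
    """Everything one synthetic or real run produces."""

    genome: GenomeSequence
    cdna_reads: list[AlignedRead]
    cdna_profile: EndProfile
    sites: list[PolyASiteCandidate]
    drna_profile: Optional[EndProfile] = None
    evaluations: dict[str, EvaluationResult] = field(default_factory=dict)
    evaluations_hc: dict[str, EvaluationResult] = field(default_factory=dict)
    features: dict = field(default_factory=dict)


def detect_from_files(
    bam_path: str | Path,
    fasta_path: str | Path,
    cfg: PipelineConfig | None = None,
    contig: str | None = None,
) -> tuple[GenomeSequence, list[AlignedRead], EndProfile, list[PolyASiteCandidate]]:
    """Load one contig's reads and run detection."""
    cfg = cfg or PipelineConfig()
    genomes = load_genome(fasta_path)
    if contig is None:
        contig = next(iter(genomes))
    genome = genomes[contig]
    reads = load_reads(bam_path, genomes, cfg.detection)
    reads = [r for r in reads if r.contig == contig]
    profile = build_end_profile(reads, contig, len(genome))
    sites = detect_sites(profile, genome, cfg.detection)
    return genome, reads, profile, sites


def classify_experiments(
    genome: GenomeSequence,
    experiments: dict[str, tuple[EndProfile, list[PolyASiteCandidate]]],
    cfg: PipelineConfig | None = None,
) -> list[PolyASiteCandidate]:
    """Classify per experiment, merge the calls, then apply the exclusion."""
    cfg = cfg or PipelineConfig()
    per_exp: dict[str, list[PolyASiteCandidate]] = {}
    for name, (profile, sites) in experiments.items():
        per_exp[name] = classify_sites(
            sites, genome, profile, cfg.classifier, apply_exclusion=False)
    if len(per_exp) == 1:
        merged = next(iter(per_exp.values()))
    else:
        merged = merge_experiment_calls(per_exp, cfg.classifier)
    from .ts_classifier import exclude_near_tes
    exclude_near_tes(merged, cfg.classifier)
    return merged


def evaluate_all(
    sites: list[PolyASiteCandidate],
    genome: GenomeSequence,
    drna_profile: EndProfile,
    polyadb=None,
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, EvaluationResult], dict[str, EvaluationResult]]:
    """All filters, overall and high-confidence-only."""
    cfg = cfg or PipelineConfig()
    keep_maps, confirmed = run_all_filters(
        sites, genome, drna_profile, polyadb, cfg.validation)
    overall = {
        name: evaluate_filter(sites, keep, confirmed, name)
        for name, keep in keep_maps.items()
    }
    high_conf = {
        name: evaluate_filter(sites, keep, confirmed, name,
                              high_confidence_only=True)
        for name, keep in keep_maps.items()
    }
    return overall, high_conf


def extract_features(
    sites: list[PolyASiteCandidate],
    reads: list[AlignedRead],
    genome: GenomeSequence,
    profile: EndProfile,
    cfg: PipelineConfig | None = None,
) -> dict:
    """PAS hits, composition, end heatmap and tail distributions."""
    cfg = cfg or PipelineConfig()
    for site in sites:
        site.pas = seq_features.find_pas(genome, site, cfg.features)
    assignment = seq_features.assign_reads_to_sites(
        reads, sites, cfg.detection.window)
    measurements = {}
    for read_list in assignment.values():
        for read in read_list:
            measurements[read.read_id] = seq_features.measure_tail(
                read, cfg.features)
    return {
        "pas_histogram": seq_features.pas_distance_histogram(sites),
        "composition": seq_features.nucleotide_composition(
            sites, genome, cfg.features),
        "heatmap": seq_features.end_position_heatmap(sites, profile, cfg.features),
        "tails": seq_features.tail_length_distribution(
            measurements, assignment, sites),
        "assignment": assignment,
        "measurements": measurements,
    }


def run_synthetic_study(
    cfg: PipelineConfig | None = None,
    workdir: str | Path | None = None,
) -> tuple[StudyResult, list[synth_fixtures.TruthRecord]]:
    """Simulate a fixture bundle and push it through the whole pipeline.

    When ``workdir`` is given, SAM/FASTA/truth files are written there and
    re-loaded through the standard readers (exercising the I/O path);
    otherwise reads are built in memory through the same SAM text.
    """
    import tempfile

    cfg = cfg or PipelineConfig()
    sim = cfg.simulation
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = tmp.name
    paths = synth_fixtures.generate_bundle(sim, workdir)
    genome, cdna_reads, cdna_profile, sites = detect_from_files(
        paths["cdna"], paths["genome"], cfg)
    sites = classify_experiments(
        genome, {"cdna": (cdna_profile, sites)}, cfg)
    genomes = {genome.contig_name: genome}
    drna_reads = load_reads(paths["drna"], genomes, cfg.detection)
    drna_profile = build_end_profile(drna_reads, genome.contig_name, len(genome))
    evaluations, evaluations_hc = evaluate_all(
        sites, genome, drna_profile, None, cfg)
    features = extract_features(sites, cdna_reads, genome, cdna_profile, cfg)
    truth = synth_fixtures.read_truth(paths["truth_tsv"])
    result = StudyResult(
        genome=genome, cdna_reads=cdna_reads, cdna_profile=cdna_profile,
        sites=sites, drna_profile=drna_profile, evaluations=evaluations,
        evaluations_hc=evaluations_hc, features=features,
    )
    return result, truth


def match_sites_to_truth(
    sites: list[PolyASiteCandidate],
    truth: list[synth_fixtures.TruthRecord],
    tolerance: int = 10,
) -> dict[tuple[str, int, str], Optional[PolyASiteCandidate]]:
    """Nearest detected site (same strand, within tolerance) per truth locus."""
    matches: dict[tuple[str, int, str], Optional[PolyASiteCandidate]] = {}
    for rec in truth:
        pool = [s for s in sites
                if s.contig == rec.contig and s.strand == rec.strand
                and abs(s.pos - rec.pos) <= tolerance]
        matches[(rec.contig, rec.pos, rec.strand)] = (
            min(pool, key=lambda s: abs(s.pos - rec.pos)) if pool else None)
    return matches
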