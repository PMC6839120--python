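"""Configuration objects for every numeric threshold in the pipeline.

All thresholds carry the defaults of the published filtering rules; every one
can be overridden from a YAML file or from CLI flags.  A configuration is a
plain nested dataclass so a run manifest can serialize it losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: The 12 most commonly used human polyadenylation-signal hexamers, ordered
#: most-common-first.  Editable: pass your own ordered list to find_pas.
DEFAULT_PAS_MOTIFS: tuple[str, ...] = (
    "AATAAA",
    "ATTAAA",
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
)


@dataclass
class DetectionConfig:
    """Candidate poly(A)-site detection thresholds.

    A genomic position becomes a candidate when at least ``min_reads``
    poly(A)+ reads and at least ``min_frac`` of the same-strand overlapping
    reads end exactly there; within any ``window`` nt only the position with
    the most poly(A)+ read endings survives.
    """

    min_reads: int = 2
    min_frac: float = 0.001
    window: int = 21
    high_confidence_min: int = 10  # high confidence iff window_support > this

    # Poly(A)-evidence rule for cDNA soft clips: the 3' soft clip must start
    # with >= polya_min_a adenines within its first polya_window bases
    # (i.e. at most one non-A among the first 11 by default).
    polya_min_a: int = 10
    polya_window: int = 11


@dataclass
class ClassifierConfig:
    """Constants of the template-switching classifier.

    ``logistic_cap``/``logistic_rate``/``logistic_offset`` parameterize the
    support-fraction threshold cap / (1 + 2^(-rate * (1/(20-n) - offset)))
    where n is the A-count of the upstream region.
    """

    arich_site_min: int = 3
    logistic_cap: float = 0.8
    logistic_rate: float = 100.0
    logistic_offset: float = 0.08
    window: int = 21
    opposite_strand_fold: float = 100.0
    exclusion_distance: int = 50
    read_arich_run: int = 3

    def __post_init__(self) -> None:
        if self.exclusion_distance < 0:
            raise ValueError("exclusion_distance must be >= 0")
        for name in ("arich_site_min", "logistic_cap", "logistic_rate",
                     "logistic_offset", "window", "opposite_strand_fold",
                     "read_arich_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ValidationConfig:
    """dRNA confirmation and baseline-filter thresholds."""

    drna_min_frac: float = 0.005
    window: int = 21
    ip_min_run: int = 6        # internal priming: discard if run of >= 6 As
    ip_min_a_in_20: int = 12   # ... or >= 12 As in the upstream 20 nt
    sqanti_min_a_in_20: int = 17  # SQANTI-style: > 80% As in upstream 20 nt
    polyadb_window: int = 21


@dataclass
class FeaturesConfig:
    """Sequence-feature extraction parameters."""

    pas_upstream: int = 40
    pas_expected_distance: int = 25
    pas_motifs: tuple[str, ...] = DEFAULT_PAS_MOTIFS
    tail_mapped_nt: int = 30    # 3'-terminal mapped bases entering the query
    tail_clip_nt: int = 150     # leading soft-clip bases entering the query
    tail_target_nt: int = 180   # length of the poly(A) target
    sw_match: int = 2
    sw_mismatch: int = -3
    sw_gap: int = -3
    composition_flank: int = 50
    heatmap_flank: int = 10


@dataclass
class SimulationConfig:
    """Synthetic-fixture generator settings.

    The defaults define the study conditions every end-to-end test runs
    under: 40 genuine TESs (8 of them with a genuine A-rich upstream run of
    ``arich_tes_run`` As, the class the internal-priming baseline wrongly
    discards), 30 template-switching artifacts at loci with only 3-5 As, and
    10 internal-priming artifacts with >= 12 upstream As and primer-length
    tails.  Genuine and TS tails share one N(tail_mean, tail_sd) distribution.
    """

    seed: int = 1
    genome_length: int | None = None  # None: derived from locus count/spacing
    gc_content: float = 0.5
    n_tes: int = 40
    n_arich_tes: int = 8            # subset of n_tes with A-rich upstream
    arich_tes_run: int = 6
    n_ts_artifacts: int = 30
    n_ip_artifacts: int = 10
    artifact_acount_range: tuple[int, int] = (3, 5)
    ip_upstream_a: int = 12
    tes_cleavage_scale: float = 1.0  # discrete Laplace scale, |offset| <= 6
    tail_mean: float = 50.0
    tail_sd: float = 15.0
    tail_min: int = 5
    ip_tail_len: float = 20.0
    ip_tail_sd: float = 2.0
    cdna_depth: int = 100           # poly(A)+ reads per genuine TES
    artifact_support: int = 20      # poly(A)+ reads per artifact locus
    tes_background: int = 20        # non-poly(A) cDNA reads spanning a TES
    artifact_background: int = 400  # ... spanning an artifact locus
    drna_depth: int = 50            # dRNA reads ending at each genuine TES
    drna_background: int = 200      # dRNA reads spanning artifact loci
    pas_distance: int = 25
    locus_spacing: int = 500
    contig: str = "synth1"

    @property
    def n_loci(self) -> int:
        return self.n_tes + self.n_ts_artifacts + self.n_ip_artifacts

    def resolved_genome_length(self) -> int:
        if self.genome_length is not None:
            return self.genome_length
        return 2 * 600 + self.n_loci * self.locus_spacing


@dataclass
class PipelineConfig:
    """Top-level bundle carried through CLI runs and manifests."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        for fld in dataclasses.fields(cls):
            if fld.name in data:
                sub = dict(data[fld.name])
                sub_cls = fld.default_factory  # type: ignore[misc]
                for key in ("artifact_acount_range", "pas_motifs"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[fld.name] = sub_cls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
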