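"""Shared fixtures: genomes built from upstream strings, SAM builders, and
one session-scoped synthetic study every end-to-end test reads from."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from polyatrim import pipeline
from polyatrim.config import PipelineConfig
from polyatrim.io_alignments import GenomeSequence, reverse_complement


def genome_with_upstream(prox_first: str, strand: str = "+",
                         site_base: str = "G", pad: str = "") -> tuple[GenomeSequence, int]:
    """Build a one-contig genome whose strand-aware upstream sequence at the
    returned site position equals ``prox_first`` (proximal base first)."""
    if strand == "+":
        seq = pad + prox_first[::-1] + site_base + pad
        pos = len(pad) + len(prox_first)
    else:
        seq = pad + reverse_complement(site_base) + \
            prox_first.translate(str.maketrans("ACGTN", "TGCAN")) + pad
        pos = len(pad)
    return GenomeSequence("t", seq), pos


def write_sam(path, contig: str, length: int, rows: list[str]) -> str:
    """Write a SAM file with a single-@SQ header and the given body rows."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for row in rows:
            fh.write(row + "\n")
    return str(path)


def sam_row(name: str, flag: int, contig: str, pos1: int, cigar: str,
            seq: str, mapq: int = 60) -> str:
    return f"{name}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 40 TES, 30 TS, 10 IP, seeded."""
    return pipeline.run_synthetic_study(PipelineConfig())


@pytest.fixture(scope="session")
def truth_matches(default_study):
    result, truth = default_study
    matches = pipeline.match_sites_to_truth(result.sites, truth)
    kind_by_key = {}
    for rec in truth:
        site = matches[(rec.contig, rec.pos, rec.strand)]
        if site is not None:
            kind_by_key[site.key()] = rec.kind
    return matches, kind_by_key


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
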