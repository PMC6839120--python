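"""Adenine-content measures of the region upstream of a poly(A) site.

The central measure is the halting-counter A-count: walk the 20 nt upstream
of the site (strand-aware, proximal base first), add 1 for every A and
subtract 1 for anything else, stop as soon as the counter reaches -1 or the
window is exhausted, and report the highest counter value seen.  Compared to
a plain run length or window count this weights adenines near the cleavage
position more heavily while still seeing the broader neighbourhood.

The classical measures used by the internal-priming and SQANTI-style
baselines (longest A run, As per 20-nt window) are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_alignments import GenomeSequence


@dataclass(frozen=True)
class ARichAssessment:
    """A-richness summary of one site's upstream 20-nt window."""

    a_count: int
    max_consecutive_a: int
    a_in_20: int

    def __post_init__(self) -> None:
        if self.a_count > self.a_in_20:
            raise ValueError("a_count cannot exceed a_in_20")


def a_count_upstream(
    genome: GenomeSequence, pos: int, strand: str, window: int = 20
) -> int:
    """Halting-counter A-count of the ``window`` nt strictly upstream of ``pos``.

    The site base itself is not part of the window.  N counts as a non-A.
    The window is truncated at contig boundaries.
    """
    counter = 0
    best = 0
    for base in genome.upstream(pos, strand, window):
        counter += 1 if base == "A" else -1
        if counter > best:
            best = counter
        if counter == -1:
            break
    return best


def max_consecutive_a(
    genome: GenomeSequence, pos: int, strand: str, window: int = 20
) -> int:
    """Longest run of As within the strand-aware upstream window."""
    best = run = 0
    for base in genome.upstream(pos, strand, window):
        run = run + 1 if base == "A" else 0
        if run > best:
            best = run
    return best


def a_in_20(genome: GenomeSequence, pos: int, strand: str, window: int = 20) -> int:
    """Number of As in the strand-aware upstream window."""
    return genome.upstream(pos, strand, window).count("A")


def assess(genome: GenomeSequence, pos: int, strand: str, window: int = 20) -> ARichAssessment:
    return ARichAssessment(
        a_count=a_count_upstream(genome, pos, strand, window),
        max_consecutive_a=max_consecutive_a(genome, pos, strand, window),
        a_in_20=a_in_20(genome, pos, strand, window),
    )
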