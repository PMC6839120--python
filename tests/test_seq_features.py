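"""PAS scanning, composition/heatmap profiles and poly(A)-tail measurement."""

import numpy as np
import pytest
from Bio import Align

from polyatrim.config import FeaturesConfig
from polyatrim.io_alignments import AlignedRead, GenomeSequence, reverse_complement
from polyatrim.seq_features import (
    assign_reads_to_sites,
    end_offset_dispersion,
    end_position_heatmap,
    find_pas,
    measure_tail,
    nucleotide_composition,
    pas_distance_histogram,
    tail_length_distribution,
)
from polyatrim.site_detection import PolyASiteCandidate

from conftest import genome_with_upstream
from test_site_detection import profile_from_counts


def upstream_with_motifs(placements, length=40):
    """Proximal-first upstream string with hexamers ending at given distances."""
    seq = list("GCGCGT" * 7)[:length]
    for motif, distance in placements:
        # distance d: motif 3' end at proximal-first index d-1, 5' end deeper
        for i, base in enumerate(motif[::-1]):
            seq[distance - 1 + i] = base
    return "".join(seq)


def site_at(genome, pos, strand, label="TES", hc=True):
    s = PolyASiteCandidate(genome.contig_name, pos, strand, support=5,
                           window_support=20, overlap=50,
                           high_confidence=hc)
    s.classification = label
    return s


@pytest.mark.parametrize("strand", ["+", "-"])
def test_find_pas_prefers_most_common_motif(strand):
    upstream = upstream_with_motifs([("AATAAA", 25), ("ATTAAA", 15)])
    genome, pos = genome_with_upstream(upstream, strand, pad="G" * 50)
    hit = find_pas(genome, site_at(genome, pos, strand))
    assert hit.motif == "AATAAA" and hit.distance == 25 and hit.rank == 0


@pytest.mark.parametrize("strand", ["+", "-"])
def test_find_pas_tie_on_rank_minimizes_distance_to_25(strand):
    upstream = upstream_with_motifs([("AATAAA", 18), ("AATAAA", 31)])
    genome, pos = genome_with_upstream(upstream, strand, pad="G" * 50)
    hit = find_pas(genome, site_at(genome, pos, strand))
    assert hit.distance == 31  # |31-25| = 6 < |18-25| = 7


def test_find_pas_absent_motif_returns_none():
    genome, pos = genome_with_upstream("GC" * 20, "+", pad="G" * 50)
    assert find_pas(genome, site_at(genome, pos, "+")) is None


def test_find_pas_strand_mirror_invariance():
    upstream = upstream_with_motifs([("AATAAA", 25)])
    gplus, pplus = genome_with_upstream(upstream, "+", pad="G" * 50)
    gminus = GenomeSequence("t", reverse_complement(gplus.sequence))
    pminus = len(gplus.sequence) - 1 - pplus
    hit_plus = find_pas(gplus, site_at(gplus, pplus, "+"))
    hit_minus = find_pas(gminus, site_at(gminus, pminus, "-"))
    assert hit_plus == hit_minus


def test_pas_distance_histogram_per_class():
    sites = []
    for i, (label, dist) in enumerate([("TES", 25), ("TES", 25),
                                       ("TS_ARTIFACT", 12)]):
        upstream = upstream_with_motifs([("AATAAA", dist)])
        genome, pos = genome_with_upstream(upstream, "+", pad="G" * 50)
        s = site_at(genome, pos, "+", label)
        s.pas = find_pas(genome, s)
        sites.append(s)
    hist = pas_distance_histogram(sites)
    assert hist["TES"] == {25: 2}
    assert hist["TS_ARTIFACT"] == {12: 1}
    assert pas_distance_histogram([]) == {}


# ---------------------------------------------------------------- tails ----

def clip_read(clip, mapped_tail="GGGGGGGGGG", read_id="r"):
    return AlignedRead(read_id=read_id, contig="t", strand="+",
                       aln_start=0, aln_end=len(mapped_tail),
                       end3=len(mapped_tail) - 1, end5=0,
                       clip3_seq=clip, mapped_tail_seq=mapped_tail,
                       has_polyA_evidence=True)


def sw_full_dp(query, target_len=180, match=2, mismatch=-3, gap=-3):
    """Independent full Smith-Waterman with A-maximizing tie-break.

    Rows consume query bases; at every cell the best (score, As along an
    optimal path) pair is kept, where As counts query As consumed by the
    path whether matched or gapped.
    """
    L = len(query)
    H = np.zeros((L + 1, target_len + 1), dtype=np.int64)
    A = np.zeros((L + 1, target_len + 1), dtype=np.int64)
    for i in range(1, L + 1):
        a_i = 1 if query[i - 1] == "A" else 0
        s_i = match if query[i - 1] == "A" else mismatch
        for j in range(1, target_len + 1):
            options = [
                (0, 0),
                (H[i - 1][j - 1] + s_i, A[i - 1][j - 1] + a_i),
                (H[i - 1][j] + gap, A[i - 1][j] + a_i),   # query base vs gap
                (H[i][j - 1] + gap, A[i][j - 1]),         # target A vs gap
            ]
            H[i][j], A[i][j] = max(options)
    best = H.max()
    if best <= 0:
        return 0, 0
    return int(best), int(A[H == best].max())


@pytest.mark.parametrize("clip,mapped,score,length", [
    ("A" * 10, "GCGTCCGTGG", 20, 10),
    ("AAAAATAAAA", "GCGTCCGTGG", 15, 9),   # spanning the T beats splitting
    ("C" * 10, "GCGTCCGTGG", 0, 0),
    ("", "GGGGGGGGGG", 0, 0),
])
def test_measure_tail_examples(clip, mapped, score, length):
    m = measure_tail(clip_read(clip, mapped))
    assert (m.sw_score, m.tail_length) == (score, length)
    assert sw_full_dp(mapped[-30:] + clip[:150]) == (score, length)


def test_measure_tail_counts_mapped_terminal_adenines():
    # genomic As abutting the clip merge into the measured tail
    m = measure_tail(clip_read("A" * 8, "GGGGGGAAAA"))
    assert m.tail_length == 12


def test_measure_tail_matches_full_dp_on_random_queries(rng):
    bases = np.array(list("ACGT"))
    for _ in range(120):
        n = int(rng.integers(0, 60))
        clip = "".join(rng.choice(bases, size=n, p=[0.7, 0.1, 0.1, 0.1]))
        mapped = "".join(rng.choice(bases, size=10))
        m = measure_tail(clip_read(clip, mapped))
        assert (m.sw_score, m.tail_length) == sw_full_dp(mapped + clip)


def test_measure_tail_score_matches_biopython_local_aligner(rng):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3
    target = "A" * 180
    bases = np.array(list("ACGT"))
    for _ in range(200):
        n = int(rng.integers(1, 150))
        clip = "".join(rng.choice(bases, size=n, p=[0.6, 0.15, 0.15, 0.1]))
        mapped = "GCGTCCGTGG"
        m = measure_tail(clip_read(clip, mapped))
        query = mapped + clip
        expected = aligner.score(target, query) if "A" in query else 0
        assert m.sw_score == max(int(expected), 0)


def test_tail_invariant_beyond_clip_position_150():
    base_clip = "A" * 150
    m1 = measure_tail(clip_read(base_clip))
    m2 = measure_tail(clip_read(base_clip + "A" * 40))
    m3 = measure_tail(clip_read(base_clip + "C" * 40))
    assert m1.tail_length == m2.tail_length == m3.tail_length == 150


def test_tail_bounded_by_target_length():
    m = measure_tail(clip_read("A" * 150, "A" * 30))
    assert m.tail_length == 180 <= 180


# ----------------------------------------------- composition / heatmap ----

def test_composition_single_site_is_indicator():
    genome = GenomeSequence("t", "ACGT" * 60)
    site = site_at(genome, 120, "+")
    comp = nucleotide_composition([site], genome)["TES"]
    assert comp.shape == (4, 101)
    assert np.allclose(comp.sum(axis=0), 1.0)
    assert set(np.unique(comp)) == {0.0, 1.0}
    window = genome.sequence[70:171]
    for col, base in enumerate(window):
        assert comp["ACGT".index(base), col] == 1.0


def test_composition_strand_symmetry():
    seq = "GATTACAGGGCCC" * 20
    gplus = GenomeSequence("t", seq)
    gminus = GenomeSequence("t", reverse_complement(seq))
    pos = 130
    comp_plus = nucleotide_composition([site_at(gplus, pos, "+")], gplus)["TES"]
    comp_minus = nucleotide_composition(
        [site_at(gminus, len(seq) - 1 - pos, "-")], gminus)["TES"]
    assert np.allclose(comp_plus, comp_minus)


def test_heatmap_point_mass_and_uniform_rows():
    profile = profile_from_counts(polya={100: 30}, coverage={100: 30})
    site = site_at(GenomeSequence("t", "G" * 400), 100, "+")
    row = end_position_heatmap([site], profile)["TES"]
    assert row[10] == 1.0 and row.sum() == pytest.approx(1.0)
    assert end_offset_dispersion(row) == 0.0
    uniform = profile_from_counts(polya={p: 2 for p in range(90, 111)},
                                  coverage={100: 42})
    row = end_position_heatmap([site], uniform)["TES"]
    assert np.allclose(row, 1 / 21)
    assert end_offset_dispersion(row) > 5.0


def test_heatmap_restricted_to_high_confidence_sites():
    profile = profile_from_counts(polya={100: 30}, coverage={100: 30})
    site = site_at(GenomeSequence("t", "G" * 400), 100, "+", hc=False)
    assert end_position_heatmap([site], profile) == {}


def test_read_assignment_and_tail_distribution():
    genome = GenomeSequence("t", "G" * 400)
    sites = [site_at(genome, 100, "+", "TES"),
             site_at(genome, 200, "+", "TS_ARTIFACT")]
    reads, measurements = [], {}
    for i, (end3, tail) in enumerate([(95, 20), (105, 20), (100, 20),
                                      (200, 30), (200, 30), (250, 99)]):
        r = AlignedRead(read_id=f"r{i}", contig="t", strand="+",
                        aln_start=end3 - 50, aln_end=end3 + 1, end3=end3,
                        end5=end3 - 50, clip3_seq="A" * tail,
                        mapped_tail_seq="G" * 30, has_polyA_evidence=True)
        reads.append(r)
        measurements[r.read_id] = measure_tail(r)
    assignment = assign_reads_to_sites(reads, sites)
    assert len(assignment[sites[0].key()]) == 3   # ends within 100±10
    assert len(assignment[sites[1].key()]) == 2   # the 250-ender is orphaned
    dist = tail_length_distribution(measurements, assignment, sites)
    assert dist["TES"]["median"] == 20
    assert dist["TS_ARTIFACT"]["median"] == 30
    assert tail_length_distribution({}, {}, []) == {}
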