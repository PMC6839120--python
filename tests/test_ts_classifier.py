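"""Logistic threshold, A-rich read ends, site classification and merging."""

import numpy as np
import pytest

from polyatrim.config import ClassifierConfig
from polyatrim.io_alignments import EndProfile, GenomeSequence
from polyatrim.site_detection import PolyASiteCandidate
from polyatrim.ts_classifier import (
    EXCLUDED,
    TES,
    TS_ARTIFACT,
    classify_site,
    classify_sites,
    end_position_is_arich,
    exclude_near_tes,
    logistic_threshold,
    merge_experiment_calls,
    opposite_strand_rule,
)

from conftest import genome_with_upstream
from test_site_detection import profile_from_counts


def test_logistic_threshold_known_values():
    # n = 10: exponent -2, 2^-2 = 0.25, 0.8 / 1.25 = 0.64 exactly
    assert logistic_threshold(10) == pytest.approx(0.64, abs=1e-15)
    # n = 0: 0.8 / (1 + 2^3) = 0.8 / 9
    assert logistic_threshold(0) == pytest.approx(0.8 / 9, abs=1e-15)
    # n = 20 is the limit of the formula
    assert logistic_threshold(20) == 0.8


def test_logistic_threshold_monotone_and_bounded():
    values = [logistic_threshold(n) for n in range(21)]
    # strictly increasing over n = 0..19; the n = 20 limit caps it at 0.8
    assert all(b > a for a, b in zip(values[:20], values[1:20]))
    assert values[19] <= values[20] == 0.8
    assert all(0 < v <= 0.8 for v in values)


@pytest.mark.parametrize("n", [-1, 21])
def test_logistic_threshold_domain(n):
    with pytest.raises(ValueError):
        logistic_threshold(n)


@pytest.mark.parametrize("upstream,expected", [
    ("AAACC", True),      # run starts 1 nt upstream
    ("CAAAC", True),      # run starts 2 nt upstream
    ("CCAAA", True),      # run starts 3 nt upstream
    ("CCCAA", False),     # a 3-run would begin 4 nt upstream
    ("ACACA", False),     # no 3-run at all
    ("AACAA", False),     # only 2-runs
])
@pytest.mark.parametrize("strand", ["+", "-"])
def test_read_end_arich_geometry(upstream, expected, strand):
    genome, pos = genome_with_upstream(upstream + "GGGGG", strand, pad="GGG")
    assert end_position_is_arich(genome, pos, strand) is expected


def site_with(genome_pos, a_count_upstream_str, window_support, overlap,
              arich_ends=0, nonarich_ends=0):
    """One annotated site plus a profile realizing the window-end split."""
    genome, pos = genome_with_upstream(a_count_upstream_str, "+",
                                       pad="G" * 60)
    polya = {}
    # A-rich-ending reads pile on the site itself; non-A-rich enders go
    # 5 nt downstream where the genome is G-rich
    ends = {pos: arich_ends, pos + 5: nonarich_ends}
    profile = profile_from_counts(length=len(genome.sequence) + 80,
                                  polya={p: n for p, n in ends.items() if n},
                                  coverage={pos: overlap})
    site = PolyASiteCandidate("t", pos, "+", support=arich_ends,
                              window_support=window_support, overlap=overlap)
    from polyatrim import arich
    site.a_count = arich.a_count_upstream(genome, pos, "+")
    return site, genome, profile


def test_low_a_count_is_tes_regardless_of_support():
    site, genome, profile = site_with(0, "AAC" + "C" * 17, 2, 10000,
                                      arich_ends=2)
    assert site.a_count == 2
    assert classify_site(site, genome, profile) == TES


def test_majority_non_arich_ends_rescue_arich_site():
    upstream = "A" * 10 + "C" * 10
    site, genome, profile = site_with(0, upstream, 17, 10000,
                                      arich_ends=5, nonarich_ends=12)
    assert site.a_count == 10
    assert classify_site(site, genome, profile) == TES
    # flipped majority, negligible support fraction: artifact
    site2, genome2, profile2 = site_with(0, upstream, 17, 10000,
                                         arich_ends=12, nonarich_ends=5)
    assert classify_site(site2, genome2, profile2) == TS_ARTIFACT


def test_support_fraction_against_logistic_threshold_at_n10():
    upstream = "A" * 10 + "C" * 10
    # 50/100 = 0.5 < 0.64: artifact
    site, genome, profile = site_with(0, upstream, 50, 100, arich_ends=50)
    assert classify_site(site, genome, profile) == TS_ARTIFACT
    # 50/70 = 0.714 > 0.64: accepted
    site, genome, profile = site_with(0, upstream, 50, 70, arich_ends=50)
    assert classify_site(site, genome, profile) == TES


def test_zero_overlap_is_an_error():
    site, genome, profile = site_with(0, "C" * 20, 5, 100)
    site.overlap = 0
    with pytest.raises(ValueError):
        classify_site(site, genome, profile)


def test_criterion2_monotone_in_window_support():
    upstream = "A" * 12 + "C" * 8
    labels = []
    for ws in range(10, 90, 5):
        site, genome, profile = site_with(0, upstream, ws, 100, arich_ends=ws)
        labels.append(classify_site(site, genome, profile))
    flips = [(a, b) for a, b in zip(labels, labels[1:]) if a != b]
    assert all(a == TS_ARTIFACT and b == TES for a, b in flips)
    assert labels[-1] == TES


@pytest.mark.parametrize("ends3,opp5,expected", [
    (2, 250, True),    # 125-fold
    (2, 150, False),   # 75-fold
    (2, 200, True),    # exactly 100-fold: inclusive
])
def test_opposite_strand_rule_boundary(ends3, opp5, expected):
    profile = profile_from_counts(polya={100: ends3}, coverage={100: 1000})
    profile.ends5["-"][105] = opp5
    site = PolyASiteCandidate("t", 100, "+", support=ends3,
                              window_support=ends3, overlap=1000)
    assert opposite_strand_rule(site, profile) is expected


def test_opposite_strand_rule_overrides_tes_call():
    genome = GenomeSequence("t", "G" * 400)
    profile = profile_from_counts(polya={100: 50}, coverage={100: 60})
    profile.ends5["-"][100] = 50 * 100
    sites = [PolyASiteCandidate("t", 100, "+", support=50, window_support=50,
                                overlap=60, a_count=0)]
    classify_sites(sites, genome, profile)
    assert sites[0].classification == TS_ARTIFACT


def make_site(pos, strand, label, ws=20):
    s = PolyASiteCandidate("t", pos, strand, support=ws, window_support=ws,
                           overlap=100)
    s.classification = label
    return s


@pytest.mark.parametrize("artifact_pos,expected", [
    (120, EXCLUDED),       # 20 nt away
    (150, EXCLUDED),       # exactly 50: inclusive
    (151, TS_ARTIFACT),    # just beyond
])
def test_exclusion_distance(artifact_pos, expected):
    sites = [make_site(100, "+", TES), make_site(artifact_pos, "+", TS_ARTIFACT)]
    exclude_near_tes(sites)
    assert sites[1].classification == expected
    assert sites[0].classification == TES


def test_exclusion_is_strand_restricted():
    sites = [make_site(100, "-", TES), make_site(120, "+", TS_ARTIFACT)]
    exclude_near_tes(sites)
    assert sites[1].classification == TS_ARTIFACT


def test_merge_discordant_calls_become_tes():
    merged = merge_experiment_calls({
        "exp1": [make_site(100, "+", TS_ARTIFACT, ws=30)],
        "exp2": [make_site(103, "+", TES, ws=10)],
    })
    assert len(merged) == 1
    assert merged[0].classification == TES
    assert merged[0].pos == 100  # position from the best-supported member
    assert merged[0].source_experiment == "exp1,exp2"


def test_merge_concordant_and_singleton_calls():
    merged = merge_experiment_calls({
        "exp1": [make_site(100, "+", TES), make_site(300, "+", TS_ARTIFACT)],
        "exp2": [make_site(100, "+", TES)],
    })
    labels = {s.pos: s.classification for s in merged}
    assert labels == {100: TES, 300: TS_ARTIFACT}


def test_merge_keeps_distinct_loci_apart():
    merged = merge_experiment_calls({
        "exp1": [make_site(100, "+", TES)],
        "exp2": [make_site(115, "+", TS_ARTIFACT)],  # 15 > 10 nt apart
    })
    assert len(merged) == 2
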