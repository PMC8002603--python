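"""Conservation tracks, region/window summaries, and splice-junction PWMs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacsplice.conservation_pwm import (
    ConservationTrack,
    build_pwm,
    column_identity_scores,
    junction_window,
    label_sites,
    project_to_reference,
    read_score_track,
    region_means,
    scan_splice_candidates,
    window_means,
)
from hacsplice.degron import find_degron
from hacsplice.gene_model import GeneModel
from hacsplice.synthetic import default_gene


def test_projection_drops_reference_gap_columns():
    msa = {"ref": "A-C-GT", "sp1": "AACCGT"}
    scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    track = project_to_reference(msa, scores, "ref")
    assert track.scores.tolist() == [0.1, 0.3, 0.5, 0.6]  # columns 1,3,5,6
    assert len(track) == 4


def test_projection_requires_known_reference_and_equal_widths():
    with pytest.raises(ValueError, match="absent"):
        project_to_reference({"a": "ACGT"}, [1, 1, 1, 1], "ref")
    with pytest.raises(ValueError, match="widths"):
        project_to_reference({"ref": "ACGT", "b": "ACG"}, [1, 1, 1, 1], "ref")


def test_column_identity_scores_hand_example():
    msa = {
        "a": "AAC-",
        "b": "AGC-",
        "c": "ATCA",
    }
    scores = column_identity_scores(msa)
    # col1: 3/3 A; col2: majority ties resolve alphabetically -> 1/3;
    # col3: 3/3 C; col4: single non-gap residue -> 1/1
    assert scores.tolist() == [1.0, pytest.approx(1 / 3), 1.0, 1.0]


def test_all_gap_column_scores_zero():
    assert column_identity_scores({"a": "-", "b": "-"}).tolist() == [0.0]


def test_label_sites_regions_follow_gene_layout():
    g = GeneModel(
        "g", "TT", "ATGGCTG", "CAGTTATCACTTGAGGGAAACCTTGGCCAATT", "ATG" + "G" * 21, "AA"
    )
    deg = find_degron(g)  # STOP1 at intron site 12 -> degron = sites 1-14
    labels = label_sites(g, deg)
    assert labels[:2] == ("utr", "utr")
    assert labels[2:9] == ("exon1",) * 7
    assert labels[9:23] == ("degron",) * 14
    assert labels[23:41] == ("intron_downstream",) * 18
    assert labels[41:65] == ("exon2",) * 24
    assert labels[65:] == ("utr", "utr")


def test_region_means_and_window_labels():
    scores = [1.0] * 4 + [0.0] * 4
    labels = ("exon1",) * 4 + ("intron_downstream",) * 4
    track = ConservationTrack("ref", np.array(scores), labels)
    means = region_means(track)
    assert means == {"exon1": 1.0, "intron_downstream": 0.0}
    wins = window_means(track, window=4, step=1)
    assert len(wins) == 5
    starts, vals, labs = zip(*wins)
    assert starts == (1, 2, 3, 4, 5)
    assert vals == (1.0, 0.75, 0.5, 0.25, 0.0)
    assert labs == ("exon1", "boundary", "boundary", "boundary", "intron_downstream")


def test_window_too_wide_raises():
    track = ConservationTrack("r", np.ones(5), ("exon1",) * 5)
    with pytest.raises(ValueError):
        window_means(track, window=6)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=8, max_size=60),
    st.integers(2, 8),
)
def test_window_mean_matches_direct_average(scores, window):
    if window > len(scores):
        window = len(scores)
    track = ConservationTrack("r", np.array(scores), ("exon1",) * len(scores))
    for start, mean, label in window_means(track, window=window):
        direct = float(np.mean(scores[start - 1 : start - 1 + window]))
        assert mean == pytest.approx(direct, abs=1e-12)
        assert label == "exon1"


def test_read_score_track_skips_comments_and_checks_sites(tmp_path):
    p = tmp_path / "t.txt"
    p.write_text("# phylo scores\ntrack type=wiggle_0\n1 0.5\n2 0.75\n3 1.0\n")
    assert read_score_track(p).tolist() == [0.5, 0.75, 1.0]
    bad = tmp_path / "bad.txt"
    bad.write_text("1 0.5\n3 0.7\n")
    with pytest.raises(ValueError, match="contiguous"):
        read_score_track(bad)


def test_pwm_hand_computed_two_sequence_example():
    # column 1: A,A -> (2 + .25)/(2 + 1) = 0.75; others 0.25/3
    pwm = build_pwm(["AC", "AG"], pseudocount=0.25)
    assert pwm.frequencies[0].tolist() == pytest.approx(
        [2.25 / 3, 0.25 / 3, 0.25 / 3, 0.25 / 3]
    )
    # background: pooled counts A=2, C=1, G=1, T=0 over 4 bases
    assert pwm.background.tolist() == pytest.approx(
        [2.25 / 5, 1.25 / 5, 1.25 / 5, 0.25 / 5]
    )
    expected = math.log2((2.25 / 3) / (2.25 / 5)) + math.log2((1.25 / 3) / (1.25 / 5))
    assert pwm.score("AC") == pytest.approx(expected)


def test_pwm_uniform_training_scores_zero():
    # every base equally frequent in each column -> freq == background
    pwm = build_pwm(["AA", "CC", "GG", "TT"])
    for seq in ("AA", "CT", "GA"):
        assert pwm.score(seq) == pytest.approx(0.0, abs=1e-12)


def test_pwm_consensus_scores_highest():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    consensus = "".join(rng.choice(bases, 30))
    train = []
    for _ in range(20):
        s = list(consensus)
        for j in rng.integers(0, 30, size=3):
            s[j] = str(rng.choice(bases))
        train.append("".join(s))
    pwm = build_pwm(train)
    best = pwm.score(consensus)
    for _ in range(50):
        other = "".join(rng.choice(bases, 30))
        assert pwm.score(other) <= best


def test_pwm_rejects_bad_inputs():
    with pytest.raises(ValueError):
        build_pwm([])
    with pytest.raises(ValueError):
        build_pwm(["ACGT", "ACG"])
    pwm = build_pwm(["ACGT"])
    with pytest.raises(ValueError):
        pwm.score("ACG")


def test_junction_window_extraction():
    seq = "A" * 15 + "C" * 15 + "G" * 10
    assert junction_window(seq, 15) == "A" * 15 + "C" * 15
    with pytest.raises(ValueError):
        junction_window(seq, 14)


def test_scan_recovers_planted_junctions():
    g = default_gene()
    seq = g.unspliced
    b = g.segment_bounds()
    donor_after = b["exon1"][1]  # last exon-1 site
    acceptor_after = b["intron"][1]  # last intron site
    # train each PWM on noisy copies of its true junction window
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))

    def noisy(window, n=25, k=2):
        out = []
        for _ in range(n):
            s = list(window)
            for j in rng.integers(0, len(s), size=k):
                s[j] = str(rng.choice(bases))
            out.append("".join(s))
        return out

    pwm5 = build_pwm(noisy(junction_window(seq, donor_after)))
    pwm3 = build_pwm(noisy(junction_window(seq, acceptor_after)))
    top = scan_splice_candidates(seq, pwm5, pwm3, top_k=1)
    assert top[0][:2] == (donor_after, acceptor_after)
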