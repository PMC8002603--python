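"""Intron-encoded degron detection and sequence-similarity scoring."""

from __future__ import annotations

import functools

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from hacsplice.degron import (
    AA_SCORING,
    NT_SCORING,
    DegronStatus,
    categorize_identity,
    degron_similarity,
    find_degron,
    global_align,
)
from hacsplice.gene_model import GeneModel

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_global_score(a: str, b: str, scoring) -> float:
    """Exhaustive recursion over all global alignments with affine gaps.

    Feasible for sequences up to ~8 residues; used to validate the
    production aligner's optimal score independent of its implementation.
    """

    def sub(x: str, y: str) -> float:
        if scoring.use_blosum62:
            return float(BLOSUM62[x, y])
        return scoring.match if x == y else scoring.mismatch

    def gap_cost(length: int) -> float:
        return scoring.gap_open + scoring.gap_extend * (length - 1) if length else 0.0

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub(a[i], b[j]) + best(i + 1, j + 1))
        # gap blocks of every possible length (affine cost paid once per block)
        for k in range(1, len(a) - i + 1):
            options.append(-gap_cost(k) + _after_gap(i + k, j, "a"))
        for k in range(1, len(b) - j + 1):
            options.append(-gap_cost(k) + _after_gap(i, j + k, "b"))
        return max(options)

    @functools.lru_cache(maxsize=None)
    def _after_gap(i: int, j: int, which: str) -> float:
        # after a maximal gap block in `which`, the next move cannot extend
        # the same gap (it was maximal), so allow substitution or the other gap
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub(a[i], b[j]) + best(i + 1, j + 1))
        if which != "a":
            for k in range(1, len(a) - i + 1):
                options.append(-gap_cost(k) + _after_gap(i + k, j, "a"))
        if which != "b":
            for k in range(1, len(b) - j + 1):
                options.append(-gap_cost(k) + _after_gap(i, j + k, "b"))
        return max(options) if options else float("-inf")

    return best(0, 0)


def _gene(exon1, intron, exon2="ATG" + "G" * 21, utr5="", utr3=""):
    return GeneModel("g", utr5, exon1, intron, exon2, utr3)


def test_hand_traced_found_case():
    g = _gene("ATGGCTG", "CAGTTATCACTTGAGGGAAACCTTGGCCAATT")
    r = find_degron(g)
    assert r.status is DegronStatus.FOUND
    assert r.stop1_intron_pos == 12
    assert r.carried_nt == "G"
    assert r.degron_nt == "CAGTTATCACTTGA"
    assert r.degron_aa == "AVIT"
    assert r.truncated_orf_nt_len == 21
    assert r.truncated_protein_aa_len == 6


def test_no_stop1_when_intron_frame_is_open():
    g = _gene("ATGGCTGCA", "GCTGCAGCTGCAGCTGCAGCT" + "GCA" * 4)
    r = find_degron(g)
    assert r.status is DegronStatus.NO_STOP1
    assert r.degron_aa == "" and r.stop1_intron_pos is None


def test_too_short_when_stop_arrives_before_min_sense_codons():
    # carry 0: first full codon of the frame is already a stop
    g = _gene("ATGGCTGCA", "TAA" + "GCA" * 10)
    r = find_degron(g)
    assert r.status is DegronStatus.TOO_SHORT


def test_stop_in_straddling_codon_is_too_short():
    # carry 2 ("GA"): straddling codon GA+A -> no; force TA+A = stop
    g = _gene("ATGGCTGCATA", "A" + "GCAGCAGCA" + "TGA" + "GCA" * 5)
    r = find_degron(g)
    assert r.status is DegronStatus.TOO_SHORT


def test_min_sense_codons_threshold_exact():
    # exactly 3 sense codons then TGA -> FOUND; 2 -> TOO_SHORT
    found = find_degron(_gene("ATGGCTGCA", "GCAGCAGCATGA" + "C" * 10))
    short = find_degron(_gene("ATGGCTGCA", "GCAGCATGA" + "C" * 13))
    assert found.status is DegronStatus.FOUND and found.degron_aa == "AAA"
    assert short.status is DegronStatus.TOO_SHORT


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGT", min_size=30, max_size=90))
def test_found_degron_frame_consistency(intron):
    g = _gene("ATGGCTGCAT", intron)  # 1 nt carried into the intron
    r = find_degron(g)
    if r.status is not DegronStatus.FOUND:
        return
    frame = r.carried_nt + intron
    stop_start = len(r.carried_nt) + r.stop1_intron_pos - 1
    assert frame[stop_start : stop_start + 3] in {"TAA", "TAG", "TGA"}
    # degron_nt covers intron site 1 through the end of STOP1
    assert len(r.degron_nt) == r.stop1_intron_pos + 2
    # the peptide translates the carried nt plus the intron up to STOP1
    assert len(r.degron_aa) * 3 + 3 == len(r.carried_nt) + len(r.degron_nt)
    assert r.truncated_protein_aa_len * 3 + 3 == r.truncated_orf_nt_len


def test_global_align_hand_example():
    assert global_align("AVIT", "AVITCCC") == ("AVIT---", "AVITCCC", 5.0)


def test_global_align_identical_nt():
    assert global_align("ACGT", "ACGT", NT_SCORING) == ("ACGT", "ACGT", 8.0)


def test_global_align_rejects_empty():
    with pytest.raises(ValueError):
        global_align("", "AVIT")


# exclude A/C/G/T so alphabet auto-detection always reads these as protein
aa_strategy = st.text(alphabet="DEFHIKLMNPQRSVWY", min_size=1, max_size=6)
nt_strategy = st.text(alphabet="ACGT", min_size=1, max_size=7)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(aa_strategy, aa_strategy)
def test_aa_alignment_score_matches_exhaustive_oracle(a, b):
    _, _, score = global_align(a, b, AA_SCORING)
    assert score == pytest.approx(oracle_global_score(a, b, AA_SCORING))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(nt_strategy, nt_strategy)
def test_nt_alignment_score_matches_exhaustive_oracle(a, b):
    _, _, score = global_align(a, b, NT_SCORING)
    assert score == pytest.approx(oracle_global_score(a, b, NT_SCORING))


def test_degron_similarity_counts_identical_columns():
    rep = degron_similarity("AVITAAAAAA", "AVITCCCCCC")
    assert rep.n_identical == 4
    assert rep.length_ref == 10
    assert rep.category == "medium_low"


def test_degron_similarity_self_is_high():
    rep = degron_similarity("FPAPEPLPFQ", "FPAPEPLPFQ")
    assert rep.n_identical == 10 and rep.category == "high"


@pytest.mark.parametrize(
    "frac,cat",
    [
        (1.0, "high"),
        (0.9, "high"),
        (0.899, "medium"),
        (0.5, "medium"),
        (0.499, "medium_low"),
        (1 / 3, "medium_low"),
        (0.32, "low"),
        (0.0, "low"),
    ],
)
def test_identity_category_boundaries(frac, cat):
    assert categorize_identity(frac) == cat
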