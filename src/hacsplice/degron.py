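"""Intronic STOP1 / degron identification and cross-species comparison.

In the unspliced transcript of a single-intron gene, translation that
starts in exon 1 runs past the 5' splice site into the intron and stops
at the first in-frame intronic stop codon (STOP1).  The intron sequence
from its first nucleotide through STOP1 is the putative degron-coding
region; because the exonic part of the reading frame need not end on a
codon boundary, up to two nucleotides from the 3' end of exon 1 are
carried over to complete the first intron codon.

Degron peptides from different species are compared by Needleman-Wunsch
global alignment (Biopython's PairwiseAligner) against a reference
degron, counting identical aligned residues and binning the identity
fraction into similarity categories.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .gene_model import GeneModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = set("ACGT")


class DegronStatus(str, enum.Enum):
    FOUND = "FOUND"
    NO_STOP1 = "NO_STOP1"
    TOO_SHORT = "TOO_SHORT"


@dataclass(frozen=True)
class DegronResult:
    """Location and translation of the putative intron-encoded degron.

    ``stop1_intron_pos`` is the 1-based start of the stop triplet within
    the intron.  ``degron_nt`` runs from intron site 1 through the end of
    STOP1; ``carried_nt`` are the 0-2 exon-1 nucleotides completing the
    first codon; ``degron_aa`` are the translated sense codons (STOP1
    excluded).  ``truncated_orf_nt_len`` spans start codon through STOP1
    inclusive.
    """

    status: DegronStatus
    stop1_intron_pos: int | None = None
    degron_nt: str = ""
    carried_nt: str = ""
    degron_aa: str = ""
    truncated_orf_nt_len: int | None = None
    truncated_protein_aa_len: int | None = None


def find_degron(g: GeneModel, min_sense_codons: int = 3) -> DegronResult:
    """Locate STOP1 and the degron by continuing the exon-1 frame into the intron.

    Status is TOO_SHORT when fewer than ``min_sense_codons`` sense codons
    precede STOP1 (such stretches are too short to act as degradation
    signals), and NO_STOP1 when the frame exits the intron without hitting
    a stop codon lying wholly within it.
    """
    cds_exon1 = g.exon1[g.start_codon_offset :]
    # nucleotides left over after the last complete exon-1 codon; they start
    # the first codon that continues into the intron
    carry_len = len(cds_exon1) % 3
    carried_nt = g.exon1[-carry_len:] if carry_len else ""
    # frame enters the intron offset by the carried nucleotides
    frame = carried_nt + g.intron
    stop_frame_idx = None  # 0-based codon start within `frame`
    for i in range(0, len(frame) - 2, 3):
        codon = frame[i : i + 3]
        if codon in STOP_CODONS:
            if i < carry_len:
                # stop straddles the exon/intron boundary: translation ends
                # before any intronic sense codon is made
                return DegronResult(status=DegronStatus.TOO_SHORT)
            stop_frame_idx = i
            break
    if stop_frame_idx is None:
        return DegronResult(status=DegronStatus.NO_STOP1)

    stop1_intron_pos = stop_frame_idx - carry_len + 1  # 1-based within intron
    degron_nt = g.intron[: stop1_intron_pos + 2]
    coding = frame[:stop_frame_idx]  # sense codons: carried nt + intron up to STOP1
    n_sense = len(coding) // 3
    degron_aa = str(Seq(coding).translate()) if coding else ""

    exonic_cds_len = len(cds_exon1) - carry_len
    orf_len = exonic_cds_len + len(carried_nt) + len(degron_nt)
    result = DegronResult(
        status=DegronStatus.FOUND if n_sense >= min_sense_codons else DegronStatus.TOO_SHORT,
        stop1_intron_pos=stop1_intron_pos,
        degron_nt=degron_nt,
        carried_nt=carried_nt,
        degron_aa=degron_aa,
        truncated_orf_nt_len=orf_len,
        truncated_protein_aa_len=orf_len // 3 - 1,
    )
    assert orf_len % 3 == 0
    return result


@dataclass(frozen=True)
class AlignScoring:
    """Needleman-Wunsch scoring; defaults depend on the alphabet."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 1.0
    use_blosum62: bool = False


AA_SCORING = AlignScoring(gap_open=10.0, gap_extend=1.0, use_blosum62=True)
NT_SCORING = AlignScoring(match=2.0, mismatch=-1.0, gap_open=5.0, gap_extend=1.0)


def _alphabet_of(seq: str) -> str:
    s = set(seq)
    if s <= _NT_ALPHABET:
        return "nt"
    if s <= _AA_ALPHABET | {"*"}:
        return "aa"
    raise ValueError(f"sequence contains symbols outside nucleotide and protein alphabets: {s}")


def global_align(
    a: str, b: str, scoring: AlignScoring | None = None
) -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch) alignment of two sequences.

    Returns the two gapped strings plus the alignment score.  Amino-acid
    pairs default to BLOSUM62 with gap open 10 / extend 1; nucleotide
    pairs to match +2 / mismatch -1 / gap open 5 / extend 1.  Tie-breaking
    is deterministic (Biopython's first optimal path).
    """
    if not a or not b:
        raise ValueError("global_align requires two nonempty sequences")
    kind_a, kind_b = _alphabet_of(a), _alphabet_of(b)
    if kind_a != kind_b:
        raise ValueError(f"mixed alphabets: {kind_a} vs {kind_b}")
    if scoring is None:
        scoring = AA_SCORING if kind_a == "aa" else NT_SCORING

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.use_blosum62:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb, float(aln.score)


@dataclass(frozen=True)
class SimilarityReport:
    """Identity of a query degron against the reference, with a coarse category."""

    n_identical: int
    length_ref: int
    category: str  # high / medium / medium_low / low
    aligned_ref: str
    aligned_query: str

    @property
    def fraction(self) -> float:
        return self.n_identical / self.length_ref


def categorize_identity(fraction: float) -> str:
    """Bin an identity fraction: >=90% high, 50-89% medium, 33-49% medium-low, <33% low."""
    if fraction >= 0.90:
        return "high"
    if fraction >= 0.50:
        return "medium"
    if fraction >= 0.33:
        return "medium_low"
    return "low"


def degron_similarity(ref_aa: str, query_aa: str) -> SimilarityReport:
    """Count identical residues between two degron peptides after global alignment.

    Identities are counted only at columns where both sequences have a
    residue; the category derives from n_identical / len(ref).
    """
    sa, sb, _ = global_align(ref_aa, query_aa)
    n_ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return SimilarityReport(
        n_identical=n_ident,
        length_ref=len(ref_aa),
        category=categorize_identity(n_ident / len(ref_aa)),
        aligned_ref=sa,
        aligned_query=sb,
    )
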