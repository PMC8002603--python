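"""Synthetic inputs: isoform-mixture read sets and ortholog gene families.

``simulate_reads`` emulates a sequencing library drawn from a two-isoform
transcript pool (spliced and unspliced forms of one single-intron gene).
``spliced_fraction`` is the fraction of transcript *molecules* in spliced
form; reads are sampled the way shotgun libraries sample a pool — each
molecule contributes reads in proportion to the number of read start
positions it offers — so reads overlapping any junction are an unbiased
sample of the isoform mixture.  Reads acquire i.i.d. substitution errors,
optional 3' poly-A tails (geometric length; a ribosome-profiling library
artifact, off by default), and optional exact duplicates, then go out as
FASTQ-style records.

``simulate_family`` derives ortholog genes from an ancestor by independent
per-site substitution at region-specific rates (exons slow, degron
intermediate, downstream intron fast), while preserving the start codon
and, per species, planting the wanted degron outcome: an intact STOP1 at
the ancestral position, an early stop that leaves too few sense codons to
be a degron, or no in-frame intronic stop at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .degron import STOP_CODONS, DegronStatus, find_degron
from .gene_model import GeneModel
from .seqio import SeqRecord

BASES = "ACGT"


def default_gene(seed: int = 20210317) -> GeneModel:
    """A compact single-intron gene used as the default simulation subject.

    Sizes are scaled down from a typical yeast single-intron transcript so
    junction coverage is high at moderate read counts: 40 nt UTRs, a 120 nt
    first exon, a 75 nt intron carrying an in-frame stop at sites 31-33
    (a 33 nt degron region), and a 90 nt second exon.
    """
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    utr5 = rand(40)
    # exon1: ATG then sense codons only (no in-frame stop), length 120 = 40 codons
    codons = []
    while len(codons) < 39:
        c = rand(3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    exon1 = "ATG" + "".join(codons)
    # intron: frame continues cleanly (exon1 length % 3 == 0, no carry);
    # sense codons for sites 1-30, TGA at 31-33, free sequence after
    intron_codons = []
    while len(intron_codons) < 10:
        c = rand(3)
        if c not in STOP_CODONS:
            intron_codons.append(c)
    tail = rand(42)
    intron = "".join(intron_codons) + "TGA" + tail
    exon2 = rand(90)
    utr3 = rand(40)
    return GeneModel(
        gene_id="synthetic_gene",
        utr5=utr5,
        exon1=exon1,
        intron=intron,
        exon2=exon2,
        utr3=utr3,
    )


@dataclass(frozen=True)
class ReadSimConfig:
    gene: GeneModel
    spliced_fraction: float
    n_reads: int = 20000
    read_len: int = 50
    error_rate: float = 0.005
    polya_tail: float = 0.0  # geometric mean tail length; 0 disables (RNA-Seq-like)
    duplication_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spliced_fraction", "error_rate", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.polya_tail < 0:
            raise ValueError("polya_tail must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for a simulated read set."""

    spliced_fraction: float
    seed: int
    isoforms: tuple[str, ...]  # per read: 'spliced' or 'unspliced'
    starts: tuple[int, ...]  # 0-based start on the source transcript


def simulate_reads(cfg: ReadSimConfig) -> tuple[list[SeqRecord], TruthRecord]:
    """Draw reads from the two-isoform pool; deterministic under a fixed seed."""
    spliced = cfg.gene.spliced
    unspliced = cfg.gene.unspliced
    for name, t in (("spliced", spliced), ("unspliced", unspliced)):
        if len(t) < cfg.read_len:
            raise ValueError(
                f"{name} transcript ({len(t)} nt) shorter than read length {cfg.read_len}"
            )
    rng = np.random.default_rng(cfg.seed)
    n_start_s = len(spliced) - cfg.read_len + 1
    n_start_u = len(unspliced) - cfg.read_len + 1
    # molecule fraction * molecule length-in-starts = read sampling weight
    w_s = cfg.spliced_fraction * n_start_s
    w_u = (1.0 - cfg.spliced_fraction) * n_start_u
    p_spliced = w_s / (w_s + w_u)

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    records: list[SeqRecord] = []
    isoforms: list[str] = []
    starts: list[int] = []
    is_spliced = rng.random(cfg.n_reads) < p_spliced
    for i in range(cfg.n_reads):
        if is_spliced[i]:
            src, n_start, iso = spliced, n_start_s, "spliced"
        else:
            src, n_start, iso = unspliced, n_start_u, "unspliced"
        start = int(rng.integers(0, n_start))
        seq = np.frombuffer(src[start : start + cfg.read_len].encode(), dtype=np.uint8).copy()
        err = rng.random(cfg.read_len) < cfg.error_rate
        for j in np.flatnonzero(err):
            choices = base_arr[base_arr != seq[j]]
            seq[j] = rng.choice(choices)
        read = seq.tobytes().decode()
        if cfg.polya_tail > 0:
            p = 1.0 / (cfg.polya_tail + 1.0)
            tail_len = int(rng.geometric(p)) - 1  # support {0, 1, ...}, mean = polya_tail
            read += "A" * tail_len
        records.append(SeqRecord(f"read{i + 1}", read, (40,) * len(read)))
        isoforms.append(iso)
        starts.append(start)

    if cfg.duplication_rate > 0:
        dup = rng.random(cfg.n_reads) < cfg.duplication_rate
        for i in np.flatnonzero(dup):
            rec = records[i]
            records.append(SeqRecord(f"{rec.id}_dup", rec.seq, rec.qual))
            isoforms.append(isoforms[i])
            starts.append(starts[i])

    truth = TruthRecord(
        spliced_fraction=cfg.spliced_fraction,
        seed=cfg.seed,
        isoforms=tuple(isoforms),
        starts=tuple(starts),
    )
    return records, truth


@dataclass(frozen=True)
class FamilySimConfig:
    ancestor: GeneModel
    n_species: int = 50
    exon_rate: float = 0.05
    degron_rate: float = 0.10
    intron_rate: float = 0.35
    utr_rate: float = 0.20
    fraction_with_stop1: float = 0.75
    fraction_too_short: float = 0.10
    min_sense_codons: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "exon_rate",
            "degron_rate",
            "intron_rate",
            "utr_rate",
            "fraction_with_stop1",
            "fraction_too_short",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_with_stop1 + self.fraction_too_short > 1.0 + 1e-12:
            raise ValueError("fraction_with_stop1 + fraction_too_short must be <= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    hit = rng.random(len(arr)) < rate
    for j in np.flatnonzero(hit):
        choices = base_arr[base_arr != arr[j]]
        arr[j] = rng.choice(choices)
    return arr.tobytes().decode()


def _frame_codons(g: GeneModel) -> tuple[int, list[int]]:
    """Carry length and 0-based intron offsets of codon starts continuing the frame.

    The first listed offset can be negative when exon nucleotides are
    carried (the straddling codon); subsequent codons lie wholly in the
    intron.
    """
    cds = g.exon1[g.start_codon_offset :]
    carry = len(cds) % 3
    first = -carry
    return carry, list(range(first, len(g.intron) - 2, 3))


def _set_intron_codon(intron: str, offset: int, codon: str) -> str:
    """Overwrite the intron triplet starting at 0-based ``offset`` (wholly intronic)."""
    return intron[:offset] + codon + intron[offset + 3 :]


def simulate_family(cfg: FamilySimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Generate ortholog gene models and a per-species truth table.

    Truth columns: species, status, stop1_intron_pos, degron_nt, degron_aa.
    Species are assigned FOUND / TOO_SHORT / NO_STOP1 outcomes by the
    configured fractions (counts rounded, FOUND takes the remainder).
    """
    anc = cfg.ancestor
    anc_deg = find_degron(anc, cfg.min_sense_codons)
    if anc_deg.status is not DegronStatus.FOUND:
        raise ValueError(f"ancestor gene must have a FOUND degron, got {anc_deg.status}")
    stop_pos = anc_deg.stop1_intron_pos
    assert stop_pos is not None
    degron_end = stop_pos + 2  # 1-based inclusive end of STOP1 in the intron

    n_too_short = round(cfg.n_species * cfg.fraction_too_short)
    n_no_stop = round(cfg.n_species * (1.0 - cfg.fraction_with_stop1 - cfg.fraction_too_short))
    n_found = cfg.n_species - n_too_short - n_no_stop
    if n_found < 0:
        raise ValueError("species fractions leave no room for FOUND species")
    statuses = (
        [DegronStatus.FOUND] * n_found
        + [DegronStatus.TOO_SHORT] * n_too_short
        + [DegronStatus.NO_STOP1] * n_no_stop
    )

    rng = np.random.default_rng(cfg.seed)
    carry, codon_offsets = _frame_codons(anc)
    species: list[GeneModel] = []
    rows = []
    for k, status in enumerate(statuses, start=1):
        utr5 = _mutate(anc.utr5, cfg.utr_rate, rng)
        exon1 = _mutate(anc.exon1, cfg.exon_rate, rng)
        exon2 = _mutate(anc.exon2, cfg.exon_rate, rng)
        utr3 = _mutate(anc.utr3, cfg.utr_rate, rng)
        deg_part = _mutate(anc.intron[:degron_end], cfg.degron_rate, rng)
        down_part = _mutate(anc.intron[degron_end:], cfg.intron_rate, rng)
        intron = deg_part + down_part
        # keep the start codon intact
        off = anc.start_codon_offset
        exon1 = exon1[:off] + "ATG" + exon1[off + 3 :]

        # keep the straddling codon stop-free: restore carried exon nt and the
        # first intron nt of that codon from the ancestor
        if carry:
            exon1 = exon1[:-carry] + anc.exon1[-carry:]
            first_len = 3 - carry
            intron = anc.intron[:first_len] + intron[first_len:]

        intronic_offsets = [o for o in codon_offsets if o >= 0]
        if status is DegronStatus.FOUND:
            # restore the planted stop, ablate any mutation-created earlier stop
            intron = _set_intron_codon(intron, stop_pos - 1, anc.intron[stop_pos - 1 : stop_pos + 2])
            for o in intronic_offsets:
                if o >= stop_pos - 1:
                    break
                if intron[o : o + 3] in STOP_CODONS:
                    intron = _set_intron_codon(intron, o, anc.intron[o : o + 3])
            truth_pos: int | None = stop_pos
        elif status is DegronStatus.TOO_SHORT:
            # plant a stop after a single sense codon: too short to be a degron.
            # With carried exon nucleotides the straddling codon is that sense
            # codon; otherwise the first wholly-intronic codon is.
            plant_idx = 0 if carry else min(1, len(intronic_offsets) - 1)
            plant_at = intronic_offsets[plant_idx]
            for o in intronic_offsets:
                if o >= plant_at:
                    break
                if intron[o : o + 3] in STOP_CODONS:
                    intron = _set_intron_codon(intron, o, anc.intron[o : o + 3])
            intron = _set_intron_codon(intron, plant_at, "TAA")
            truth_pos = plant_at + 1
        else:  # NO_STOP1: ablate every wholly-intronic in-frame stop
            for o in intronic_offsets:
                codon = intron[o : o + 3]
                if codon in STOP_CODONS:
                    intron = _set_intron_codon(intron, o, "C" + codon[1:])
            truth_pos = None

        sp = GeneModel(
            gene_id=f"species{k:02d}",
            utr5=utr5,
            exon1=exon1,
            intron=intron,
            exon2=exon2,
            utr3=utr3,
            start_codon_offset=anc.start_codon_offset,
        )
        deg = find_degron(sp, cfg.min_sense_codons)
        species.append(sp)
        rows.append(
            {
                "species": sp.gene_id,
                "status": status.value,
                "stop1_intron_pos": truth_pos,
                "degron_nt": deg.degron_nt if status is DegronStatus.FOUND else "",
                "degron_aa": deg.degron_aa if status is DegronStatus.FOUND else "",
            }
        )
    truth = pd.DataFrame(rows)
    return species, truth
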