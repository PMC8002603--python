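"""Single-intron gene representation and 40 nt junction-query construction.

A gene is held as five ordered segments: 5'UTR, exon 1, intron, exon 2,
3'UTR (UTRs may be empty).  From these, four 40 nt query sequences are
built for read mapping:

* ``EE``  — last 20 nt of exon 1 + first 20 nt of exon 2 (spliced evidence);
* ``EI5`` — last 20 nt of exon 1 + first 20 nt of intron (unspliced);
* ``EI3`` — last 20 nt of intron + first 20 nt of exon 2 (unspliced);
* ``Target`` — 20 nt upstream of the first in-frame intronic stop codon
  (STOP1), the 3 nt stop itself, and 17 nt downstream, all taken from the
  unspliced transcript (the upstream flank may reach into exon 1).

In every junction query the biological boundary falls between query sites
20 and 21 (1-based); in the Target query the stop triplet occupies sites
21-23.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .seqio import read_fasta

FLANK = 20  # nt taken from each side of a junction
QUERY_LEN = 2 * FLANK

SEGMENT_NAMES = ("utr5", "exon1", "intron", "exon2", "utr3")


@dataclass(frozen=True)
class GeneModel:
    """Five ordered sequence segments of a single-intron gene.

    ``start_codon_offset`` is the 0-based position of the ATG within exon 1.
    Coordinates derived from the model (segment starts/ends, STOP1, query
    provenance) are 1-based inclusive on the unspliced transcript.
    """

    gene_id: str
    utr5: str
    exon1: str
    intron: str
    exon2: str
    utr3: str
    start_codon_offset: int = 0

    def __post_init__(self) -> None:
        for name in SEGMENT_NAMES:
            object.__setattr__(self, name, getattr(self, name).upper().replace("U", "T"))
        if not self.exon1 or not self.exon2:
            raise ValueError(f"gene {self.gene_id!r}: exon1 and exon2 must be nonempty")
        if self.start_codon_offset < 0 or self.start_codon_offset + 3 > len(self.exon1):
            raise ValueError(
                f"gene {self.gene_id!r}: start_codon_offset {self.start_codon_offset} out of exon1"
            )
        codon = self.exon1[self.start_codon_offset : self.start_codon_offset + 3]
        if codon != "ATG":
            raise ValueError(
                f"gene {self.gene_id!r}: exon1 does not begin with ATG at offset "
                f"{self.start_codon_offset} (found {codon!r})"
            )

    @property
    def unspliced(self) -> str:
        return self.utr5 + self.exon1 + self.intron + self.exon2 + self.utr3

    @property
    def spliced(self) -> str:
        return self.utr5 + self.exon1 + self.exon2 + self.utr3

    def segment_bounds(self) -> dict[str, tuple[int, int]]:
        """1-based inclusive (start, end) of each segment on the unspliced transcript."""
        bounds = {}
        pos = 0
        for name in SEGMENT_NAMES:
            seg = getattr(self, name)
            bounds[name] = (pos + 1, pos + len(seg))
            pos += len(seg)
        return bounds

    def intron_site_to_transcript(self, intron_pos: int) -> int:
        """Map a 1-based intron site to the 1-based unspliced-transcript site."""
        return len(self.utr5) + len(self.exon1) + intron_pos


@dataclass(frozen=True)
class JunctionQuerySet:
    """The 40 nt mapping queries with their unspliced-transcript provenance.

    ``provenance`` maps each query name to its 1-based inclusive
    (start, end) span on the unspliced transcript; EE, being spliced-form
    evidence, spans the exon1 flank only up to the junction and resumes at
    exon 2 — its provenance is recorded as the exon1-flank start and the
    exon2-flank end.
    """

    ee: str
    ei5: str
    ei3: str
    target: str | None = None
    stop1_intron_pos: int | None = None
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, q in (("EE", self.ee), ("EI5", self.ei5), ("EI3", self.ei3)):
            if len(q) != QUERY_LEN:
                raise ValueError(f"query {name} must be {QUERY_LEN} nt, got {len(q)}")
        if self.target is not None and len(self.target) != QUERY_LEN:
            raise ValueError(f"query Target must be {QUERY_LEN} nt, got {len(self.target)}")

    def as_dict(self) -> dict[str, str]:
        d = {"EE": self.ee, "EI5": self.ei5, "EI3": self.ei3}
        if self.target is not None:
            d["Target"] = self.target
        return d


def build_junction_queries(
    g: GeneModel, stop1_intron_pos: int | None = None
) -> JunctionQuerySet:
    """Construct the EE/EI5/EI3 queries and, when STOP1 is given, the Target query.

    ``stop1_intron_pos`` is the 1-based start of the stop triplet within the
    intron.  The Target flanks are cut from the unspliced transcript and may
    cross the exon1/intron boundary; an error names the short segment or
    flank when 40 nt cannot be assembled.
    """
    for name in ("exon1", "intron", "exon2"):
        if len(getattr(g, name)) < FLANK:
            raise ValueError(
                f"gene {g.gene_id!r}: segment {name} is {len(getattr(g, name))} nt, "
                f"need >= {FLANK} nt for a junction flank"
            )
    ee = g.exon1[-FLANK:] + g.exon2[:FLANK]
    ei5 = g.exon1[-FLANK:] + g.intron[:FLANK]
    ei3 = g.intron[-FLANK:] + g.exon2[:FLANK]

    bounds = g.segment_bounds()
    prov = {
        "EE": (bounds["exon1"][1] - FLANK + 1, bounds["exon2"][0] + FLANK - 1),
        "EI5": (bounds["exon1"][1] - FLANK + 1, bounds["intron"][0] + FLANK - 1),
        "EI3": (bounds["intron"][1] - FLANK + 1, bounds["exon2"][0] + FLANK - 1),
    }

    target = None
    if stop1_intron_pos is not None:
        if not 1 <= stop1_intron_pos <= len(g.intron) - 2:
            raise ValueError(
                f"gene {g.gene_id!r}: STOP1 at intron site {stop1_intron_pos} "
                f"does not fit a triplet in a {len(g.intron)} nt intron"
            )
        t = g.intron_site_to_transcript(stop1_intron_pos)  # 1-based stop start
        start = t - FLANK  # 20 nt upstream
        end = t + 2 + 17  # stop triplet + 17 nt downstream
        unspliced = g.unspliced
        if start < 1:
            raise ValueError(
                f"gene {g.gene_id!r}: only {t - 1} nt upstream of STOP1 on the "
                f"unspliced transcript, need {FLANK}"
            )
        if end > len(unspliced):
            raise ValueError(
                f"gene {g.gene_id!r}: only {len(unspliced) - t - 2} nt downstream "
                f"of STOP1 on the unspliced transcript, need 17"
            )
        target = unspliced[start - 1 : end]
        prov["Target"] = (start, end)

    return JunctionQuerySet(
        ee=ee,
        ei5=ei5,
        ei3=ei3,
        target=target,
        stop1_intron_pos=stop1_intron_pos,
        provenance=prov,
    )


def load_gene_model(
    fasta_path: str | Path,
    model_tsv: str | Path | None = None,
    gene_id: str | None = None,
    start_codon_offset: int = 0,
) -> GeneModel:
    """Load a gene model from FASTA.

    Two layouts are accepted:

    * five FASTA entries with the reserved names utr5/exon1/intron/exon2/utr3
      (UTR entries may be omitted); or
    * a single full-gene FASTA entry plus ``model_tsv`` with columns
      gene_id, segment, start, end (1-based inclusive, plus strand).
    """
    records = {rec.id: rec.seq for rec in read_fasta(fasta_path)}
    if model_tsv is None:
        missing = {"exon1", "intron", "exon2"} - set(records)
        if missing:
            raise ValueError(
                f"{fasta_path}: segment-FASTA layout requires entries {sorted(missing)}"
            )
        return GeneModel(
            gene_id=gene_id or Path(fasta_path).stem,
            utr5=records.get("utr5", ""),
            exon1=records["exon1"],
            intron=records["intron"],
            exon2=records["exon2"],
            utr3=records.get("utr3", ""),
            start_codon_offset=start_codon_offset,
        )

    if len(records) != 1:
        raise ValueError(f"{fasta_path}: coordinate-TSV layout requires exactly one entry")
    (gid, full), = records.items()
    segs = {name: "" for name in SEGMENT_NAMES}
    with open(model_tsv) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = row["segment"].strip().lower()
            if name not in SEGMENT_NAMES:
                raise ValueError(f"{model_tsv}: unknown segment {name!r}")
            start, end = int(row["start"]), int(row["end"])
            if not 1 <= start <= end <= len(full):
                raise ValueError(f"{model_tsv}: segment {name} span {start}-{end} out of gene")
            segs[name] = full[start - 1 : end]
    return GeneModel(
        gene_id=gene_id or gid,
        start_codon_offset=start_codon_offset,
        **segs,
    )
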