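# Methods note

This note records the quantitative model implemented by `hacsplice`, the
parameter choices and their rationale, the scope of the synthetic-data
generators, and the numerical conventions that affect results.

## 1. Biological setting and model

`hacsplice` quantifies the splicing of a single-intron transcript — the
motivating case is a HAC1-like gene whose unconventional intron is excised by
a tRNA-ligase pathway rather than the spliceosome — from short-read sequencing
data, and characterizes the peptide encoded by the 5' portion of that intron.

A gene is modelled as five concatenated segments on the unspliced transcript:

```
5'UTR | exon 1 | intron | exon 2 | 3'UTR
```

The spliced isoform removes the intron. Translation initiated at the exon-1
start codon behaves differently on the two isoforms:

* on the **spliced** form it reads straight through the exon1/exon2 junction;
* on the **unspliced** form it runs into the intron and terminates at the
  first in-frame stop codon lying wholly within the intron (**STOP1**). The
  intronic sense codons before STOP1 encode a C-terminal peptide extension —
  a putative **degron** that destabilizes the truncated protein.

### 1.1 Junction queries

Four 40 nt query sequences, each split 20/20 around the feature of interest
(the "Target" query places a stop triplet at query sites 21–23):

| query | composition | evidence for |
|---|---|---|
| EE | last 20 nt of exon 1 + first 20 nt of exon 2 | spliced isoform |
| EI5 | last 20 nt of exon 1 + first 20 nt of intron | unspliced isoform (5' junction) |
| EI3 | last 20 nt of intron + first 20 nt of exon 2 | unspliced isoform (3' junction) |
| Target | 20 nt upstream of STOP1 + stop triplet + 17 nt downstream | ribosome footprints at STOP1 |

The Target window is taken on the unspliced transcript and its upstream flank
may cross the exon1/intron boundary when STOP1 sits fewer than 20 nt into the
intron.

### 1.2 Read mapping and the E-value filter

Reads are matched against each query by the longest shared ungapped run
(both strands; optional mismatch tolerance in extensions, default 0). A hit
with match length `w` on a read of length `L` against a query of length `q`,
in a dataset of `N` retained reads, is assigned the expectation value

```
E = (q − w) · N · (L − w) · 2^(−2w)
```

i.e. the number of alignment placements times the probability of `w`
consecutive base matches under a uniform base model. A hit is retained when
all three hold:

1. `w ≥ min_match` (default 25);
2. `E < e_cutoff` (default 1e-7);
3. `E ≤ E_critical`, where `E_critical` is the E-value of a hit with
   `w = min_match` on the same read — this makes the length threshold and the
   statistical threshold consistent per read. The comparison is `≤` so that a
   hit of exactly `min_match` bases is retained (with `<` the rule would
   contradict itself at the boundary).

A retained hit is counted for a junction only if it spans the junction:
query sites 20 and 21 for EE/EI5/EI3, sites 21 and 23 (the stop triplet) for
Target. With 40 nt queries and `min_match = 25` the span condition is
geometrically implied (any 25 nt run covers sites 20/21); it becomes an
active filter only for shorter `min_match`.

Counts are multiplicities: deduplicated reads carry their duplicate count
(the `_<count>` FASTA suffix), and `N` in the E-value is the total
multiplicity of the retained read set.

### 1.3 Splicing efficiency and translation intensity

From junction counts `N_EE`, `N_EI5`, `N_EI3`:

```
p       = N_EI5 / (N_EI5 + N_EI3)                (undefined when both are 0)
N_Total = N_EE + p·N_EI5 + (1−p)·N_EI3          (N_Total = N_EE when p undefined)
SE      = N_EE / N_Total
```

`p` apportions the unspliced evidence between the two exon–intron junctions
so that a single unspliced molecule observed at both junctions is not counted
twice. SE is reported to 3 decimals. Translation intensity, for
ribosome-footprint data, is the arithmetic mean of `N_EI5`, `N_EI3`, and
`N_Target`; it is undefined only when all four counts are zero. Counts can
also be normalized per kilobase of retained sequence.

### 1.4 Degron identification

The exon-1 coding sequence after the start codon has length `c`; the
`c mod 3` trailing nucleotides ("carried" nucleotides) begin the first codon
that continues into the intron. Reading that frame through the intron:

* a stop codon wholly within the intron is STOP1; the degron peptide is the
  translation of the sense codons before it (carried codon included);
* a stop in the codon straddling the exon/intron boundary terminates
  translation before any intronic sense codon exists → `TOO_SHORT`;
* fewer than `min_sense_codons` (default 3) sense codons before STOP1 →
  `TOO_SHORT` (too short to act as a degradation signal);
* no wholly-intronic in-frame stop → `NO_STOP1`.

### 1.5 Cross-species comparison

Degron peptides are compared to a reference by global (Needleman–Wunsch)
alignment using Biopython's `PairwiseAligner`: BLOSUM62 with gap open 10 /
extend 1 for protein, match +2 / mismatch −1 / gap open 5 / extend 1 for
nucleotide. Similarity is the count of identical aligned columns; the
identity fraction (relative to the reference length) is binned as
high ≥ 0.9 > medium ≥ 0.5 > medium_low ≥ 1/3 > low.

### 1.6 Conservation summaries

Per-site conservation scores in [0, 1] come from one of: a two-column
site/score text track; projection of per-alignment-column scores onto a
reference (columns where the reference is gapped are dropped); or the
built-in per-column identity fraction (share of non-gap residues matching
the column majority). The identity fraction is a deliberately simple
stand-in — phylogenetic conservation models such as PhastCons are out of
scope. Summaries are means per region (UTR, exon 1, degron, downstream
intron, exon 2) and sliding-window means (default 32 nt, step 1), each
window labelled by its single region or `boundary`.

### 1.7 Splice-site PWMs

Position weight matrices over 30 nt junction windows (15 nt per side) are
built with a pseudocount of 0.25 per base per column; the background is the
pooled training-base composition with the same pseudocount. Scores are
summed log2 odds. A scan over all (donor, acceptor) window pairs with
donor < acceptor ranks candidate intron placements.

## 2. Default parameters

| parameter | default | rationale |
|---|---|---|
| read min length after trimming | 50 | matches the shortest reads informative for 40 nt queries with 25 nt matches |
| poly-A trimming | on | strips oligo-dT/template-switch artifacts before dedup |
| `min_match` | 25 | more than half the query; with the E-rule, keeps per-read false-positive expectation ≪ 1 at ~10⁷ reads |
| `e_cutoff` | 1e-7 | ≈ 30× below the critical E at N ≈ 10⁷ reads |
| mismatches in extension | 0 | exact runs keep the E-value model valid |
| `min_sense_codons` | 3 | shorter peptides are implausible degradation signals |
| PWM pseudocount | 0.25 | standard light smoothing; keeps zero counts finite without flattening small training sets |
| conservation window | 32 | length of the reference degron region |

## 3. Synthetic data generators — scope and design

The generators exist to exercise the pipeline end to end with known ground
truth. They are *not* models of real library preparation.

### 3.1 Read simulator

`simulate_reads` draws reads of fixed length `rl` from a two-isoform mixture.
The configured `spliced_fraction` `f` is a **molecule** fraction. Shotgun
sampling of fixed-length reads from a molecule pool yields reads from a given
isoform in proportion to both its molecule count and the number of read start
positions it offers, so the per-read isoform probability is

```
P(spliced) = f·(Ls − rl + 1) / [ f·(Ls − rl + 1) + (1−f)·(Lu − rl + 1) ]
```

with `Ls`, `Lu` the spliced/unspliced transcript lengths. Junction-spanning
windows are equally numerous per molecule on both isoforms (one 40 nt window
each for EE and EI5/EI3 per molecule), so junction reads sample isoforms in
proportion to molecule counts and SE is an unbiased estimate of `f`. A naive
per-read Bernoulli(`f`) would over-represent the shorter (spliced) isoform's
junctions and bias SE upward by several hundredths at `f = 0.5`.

Substitution errors are i.i.d. per base at `error_rate`. Optional geometric
poly-A tails and a duplication rate exercise the trimming and deduplication
stages. **`polya_tail` defaults to 0**: appended tails are a library artifact
of poly-A-primed protocols, and simulating them revealed a genuine censoring
bias — after tail trimming and the 50 nt length filter, reads whose genomic
window ends in `A` are preferentially discarded, and the three junction
windows offer unequal numbers of surviving start positions (29/34/29 for the
default gene), shifting SE by about −0.02 at `f = 0.5`. That bias is a
property of poly-A trimming on tailed libraries, not of the estimator, so
the recovery experiment simulates untailed reads and disables trimming
rather than loosening the accuracy bound.

Everything is driven by `numpy.random.default_rng(seed)`; outputs are
byte-identical across runs for a fixed configuration.

### 3.2 Family simulator

`simulate_family` evolves an ancestor gene into `n_species` orthologs by
per-region substitution rates (no indels, so families remain column-aligned),
defaults: exon 0.05, degron 0.10, intron-downstream 0.35, UTR 0.20 —
degron conserved relative to the rest of the intron. Each species is planted
with a degron status (`FOUND` / `TOO_SHORT` / `NO_STOP1` in configurable
fractions): the start codon is always preserved, STOP1 is restored and
earlier in-frame stops reverted for `FOUND`, an early stop is planted for
`TOO_SHORT`, and all wholly-intronic in-frame stops are ablated for
`NO_STOP1`. The truth table records the planted status, STOP1 position, and
degron sequences per species.

## 4. Numerical conventions

* SE and identity fractions are reported to 3 decimals; internal arithmetic
  is double precision throughout.
* Sliding-window means use a cumulative-sum formulation (O(n) per track).
* The long-run mapper search is an O(read × query) dynamic program over
  match indicators (vectorized per diagonal), with a 13-mer prefilter in
  bulk counting when `min_match ≥ 13` and no mismatches are allowed; results
  are identical to exhaustive enumeration (asserted against a brute-force
  oracle in the test suite).
* Alignment tie-breaking follows Biopython's first optimal path; identity
  counts are invariant to which co-optimal path is reported only when the
  co-optimal alignments agree on identical columns, so reported identities
  are defined as "identity of the returned optimal alignment".
* E-values are computed in closed form; no random element.

## 5. Limitations and what is not desk-reproducible

* The published **absolute junction read counts** (and the splicing/
  translation tables built from them) come from specific SRA sequencing
  runs; reproducing them requires downloading that external raw data.
  This package reproduces the *arithmetic* on the printed counts exactly,
  not the counts themselves.
* Published **PhastCons** conservation values require the external
  multiple-genome alignments and the PhastCons software; the internal
  identity-fraction score is a simple substitute with different scale and
  smoothing.
* Published **per-species** degron identity percentages require the actual
  ortholog sequences from genome databases; the family simulator produces
  structurally analogous, not biologically identical, inputs.
* The degron finder assumes a single intron and standard genetic code, and
  reports only the first in-frame intronic stop.
* The read simulator ignores fragment-length distributions, sequence-
  dependent coverage bias, quality-score structure, and indel errors.
* The family simulator's substitution-only model cannot produce length
  variation between orthologs; real degron alignments contain indels.
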