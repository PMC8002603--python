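# hacsplice

Quantify the splicing of a single-intron transcript from short-read
sequencing data and characterize the peptide encoded by its intron.

## The problem

Some transcripts — the motivating case is a HAC1-like mRNA whose intron is
excised by a non-spliceosomal, tRNA-ligase-type pathway — exist in a cell as
a mixture of spliced and unspliced molecules, and the balance between the two
is the biological readout. On the unspliced form, translation that starts in
exon 1 runs into the intron and terminates at the first in-frame intronic
stop codon (STOP1); the short intron-encoded peptide before STOP1 can act as
a degron that destabilizes the truncated protein.

`hacsplice` answers three questions from sequencing reads and gene sequences:

1. **How efficiently is the transcript spliced?** Reads are matched against
   four 40 nt junction queries — exon1/exon2 (EE, spliced evidence),
   exon1/intron (EI5) and intron/exon2 (EI3, unspliced evidence), and a
   STOP1-centered Target window for ribosome footprints. With junction read
   counts `N_EE`, `N_EI5`, `N_EI3`:

   ```
   p       = N_EI5 / (N_EI5 + N_EI3)
   N_Total = N_EE + p·N_EI5 + (1−p)·N_EI3     (N_Total = N_EE when p is undefined)
   SE      = N_EE / N_Total
   ```

   Translation intensity TI = mean(N_EI5, N_EI3, N_Target) summarizes
   footprint density over the unspliced-specific windows.

2. **What does the intron encode?** Continuing the exon-1 reading frame into
   the intron locates STOP1 and translates the degron peptide, classifying
   each gene as `FOUND`, `TOO_SHORT` (stop before 3 sense codons), or
   `NO_STOP1`. Degrons are compared across species by global alignment
   (BLOSUM62) with identity-fraction categories.

3. **Is the degron conserved?** Per-site conservation tracks (loaded, or the
   built-in alignment identity fraction) are summarized per gene region and
   in sliding 32 nt windows; splice junctions can additionally be modelled by
   log-odds position weight matrices.

Matching uses longest ungapped runs filtered by the expectation value
`E = (q−w)·N·(L−w)·2^(−2w)` (query length `q`, match `w`, read length `L`,
`N` reads), requiring `w ≥ 25`, `E < 10⁻⁷`, `E` no worse than the per-read
critical value, and overlap of the junction site. See `docs/methods.md`
for the full model, parameter rationale, and limitations.

## Worked example

Compute splicing efficiency from published junction counts:

```python
>>> from hacsplice import JunctionCounts, splicing_efficiency
>>> s = splicing_efficiency(JunctionCounts(n_ee=140, n_ei5=1, n_ei3=0))
>>> s.p, s.n_total, s.format_se()
(1.0, 141.0, '0.993')
```

Find the intron-encoded degron of the built-in demonstration gene:

```python
>>> from hacsplice.degron import find_degron
>>> from hacsplice.synthetic import default_gene
>>> r = find_degron(default_gene())
>>> r.status.value, r.stop1_intron_pos, r.degron_aa
('FOUND', 31, 'FPAPEPLPFQ')
```

Run the whole pipeline on simulated reads. With `run.yaml`:

```yaml
outdir: out
seed: 1
simulate:
  spliced_fraction: 0.8
  n_reads: 20000
  error_rate: 0.005
preprocess:
  trim_polya: false
```

```
$ hacsplice run-all --config run.yaml
config: run.yaml
simulated 21026 reads (f=0.8, seed=1)
preprocess: kept 21026/21026 reads, 1051.3 kb
map: N_EE=2413 N_EI5=623 N_EI3=602 N_Target=656
summary:  N_EE  N_EI5  N_EI3  N_Target     p  N_Total    SE     TI ...
          2413    623    602       656 0.509  3025.68 0.798 627.00 ...
```

The recovered SE of 0.798 matches the simulated spliced molecule fraction of
0.8. Outputs land in `out/`: deduplicated reads (`reads.fastaplus`), the four
queries (`queries.fa`), per-read hits (`hits.tsv`), the summary table
(`summary.tsv`), and a stage log (`run.log`).

Individual stages are also available as subcommands (`hacsplice --help`):
`preprocess`, `build-queries`, `map`, `splicing-stats`, `find-degron`,
`degron-compare`, `conservation-windows`, `pwm`, `simulate-reads`,
`simulate-family`.

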