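# amperr — amplicon deep-sequencing error profiling

`amperr` measures the platform-specific error fingerprint of amplicon
deep-sequencing runs. Targeted resequencing of a handful of PCR amplicons at
very high depth (e.g. exonic hotspot regions of a gene such as *CREBBP*,
325–370 bp per amplicon) is only as sensitive as the sequencing platform's
intrinsic error rate: pyrosequencing (454 GS FLX) and semiconductor
sequencing (IonTorrent PGM) produce mostly homopolymer-associated indels,
while dye-terminator chemistry (Illumina MiSeq) produces mostly
substitutions. Before calling low-frequency variants, one needs to know those
baseline rates for the exact library design in hand. `amperr` computes them,
and ships a construct-aware read simulator so every statistic can be
validated end-to-end by parameter recovery against known ground truth.

It is aimed at people running two-step (universal-tailed) PCR amplicon
libraries: gene-specific primers carry universal linker tails in the first
PCR, and platform adapters plus sample barcodes are fused onto those tails in
the second PCR, so a read looks like

```
adapter5 + barcode + linker_fwd + insert + rc(linker_rev) + rc(adapter3)
```

## What it computes

Given FASTQ reads, a FASTA panel of amplicon references and a barcode sheet,
the pipeline runs demultiplex → trim → mask/filter → align → profile:

* **Quality control** — every base with Phred quality < 20 is replaced by N;
  reads with mean Phred < 25 or more than 6 N bases are removed. Per-position
  quality summaries and the read-length histogram are reported.
* **Alignment** — each insert read is aligned end-to-end against every panel
  reference in both orientations (affine-gap dynamic programming, free
  reference ends); the best (reference, strand) wins.
* **Error rates** — per run and per amplicon:
  `subst % = 100 · substituted bases / aligned bases`,
  `indel % = 100 · (inserted + deleted bases) / aligned bases`,
  plus substitutions and indel bases per read.
* **Substitution matrix** — for each reference base, the percentage read as
  each of the three other bases, tallied only outside homopolymer runs
  (≥ 4 identical bases) and GC-rich windows (≥ 80% G+C over 10 bp), with
  transition vs transversion summary rates.
* **Simulator** — generates full two-step constructs from the packaged
  synthetic panel with per-base substitution/indel probabilities, an optional
  substitution bias matrix, homopolymer-scaled indel rates, platform-like
  read-length and quality models, and a complete ground-truth event log.

## Worked example

Simulate a MiSeq-like run from the packaged panel and profile it:

```bash
amperr simulate --preset miseq --n 2000 --seed 17 --out sim/
amperr profile --reads sim/reads.fastq --refs sim/panel.fasta \
               --barcodes sim/barcodes.tsv --spec sim/construct.json --out out/
```

which prints

```
wrote 2000 reads to sim/reads.fastq
reads_in=2000 assigned=1933 kept=1931 aligned=1931 alignment_rate=100.00%
```

Here 67 reads (3.4%) were unassigned because simulated errors hit their 16 bp
barcode in more than one position — a realistic demultiplexing loss — two
reads whose 5' adapter was damaged beyond recognition were dropped, and every
surviving read aligned. `out/run_rates.tsv` then shows the recovered
run-level rates (the MiSeq preset injects substitutions at 1.53% of bases and
indels at 0.04%):

```
run	aligned_bases	aligned_reads	subst	subst_read	subst_pct	indels	indels_read	indels_pct
pooled	364869	1931	5668	2.94	1.55	169	0.09	0.05
```

i.e. the pipeline reads back the injected substitution rate to within
sampling error (1.55% observed on 365 k aligned bases, 1.53% injected) and
the injected indel rate to within a hundredth of a percent (alignment
ambiguity next to substitution clusters occasionally re-gaps a column, which
matters only at this preset's very low indel rate). `out/subst_matrix.tsv`
shows the per-base pattern (transversion-heavy for this preset). The same
library API is available in Python via `amperr.simulate_run` /
`amperr.profile_reads`.

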