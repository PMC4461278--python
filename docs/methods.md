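# Methods

## Scope and model

`amperr` estimates run-level and amplicon-level sequencing error rates from
amplicon deep-sequencing reads built with a universal two-step PCR design.
The statistical model is deliberately simple and count-based: every aligned
read column is classified as a match, a substitution, an inserted read base
or a deleted reference base, and rates are ratios of these counts,

* substitution rate (%) = 100 · substituted bases / aligned bases,
* indel rate (%) = 100 · (inserted + deleted bases) / aligned bases,

where *aligned bases* are the match + substitution columns. Indels are
counted in **bases**, not events (a 3-base insertion contributes 3); event
counts are kept as secondary tallies. Per-read figures divide by aligned
reads. The method assumes error-only input — mutation-free template, or
simulated reads — so every mismatch is a sequencing (or residual PCR) error;
distinguishing true low-frequency variants from errors is explicitly out of
scope.

## Pipeline stages

1. **Demultiplexing.** The sample barcode occupies a fixed window directly
   after the 5' adapter. A read is assigned to the unique barcode within
   `max_mismatch` (default 1) Hamming distance, with N counting as a
   mismatch. The `BarcodeSet` constructor enforces pairwise distance
   > 2·`max_mismatch`, which makes assignment provably unambiguous.
2. **Trimming.** The 5' adapter must be recognisable (pattern alignment,
   see below); then the forward linker is located just after the barcode and
   the reverse-complemented reverse linker near the read end, and the insert
   between the two cut points is kept, qualities in lockstep. Both cut
   points come from indel-tolerant pattern alignment rather than fixed
   offsets: a single indel inside a flank must not shift the cut, because a
   leaked flank base masquerades as a sequencing error downstream. The 3'
   search prefers the rightmost placement (an insert could in principle
   contain the linker sequence; the flank copy is always last). Reads whose
   adapter cannot be located are flagged and subsequently dropped at
   filtering: with end-to-end alignment (below) their flank bases would be
   miscounted as insertions.
3. **Quality masking and filtering.** Bases with Phred < 20 become N (scores
   kept); reads with arithmetic mean Phred < 25 over all positions
   (masked included) or more than 6 Ns are removed. Boundaries are strict:
   Q20 stays, mean exactly 25 stays, exactly 6 Ns stays. Pre-existing and
   masked Ns are not distinguished.
4. **Alignment.** Each insert read is aligned against every panel reference
   in both orientations and the best (reference, strand) pair wins; ties
   break by panel order, then '+' strand. The DP is read-global /
   reference-local ("glocal") with affine gaps: the read is consumed
   end-to-end, the reference ends are free. A fully local
   (Smith–Waterman) alignment was considered and rejected for this
   application: local alignment clips any negative-scoring terminal segment,
   which censors errors at read ends — with the default scoring (+2/−4),
   roughly two error columns per read end — and biases recovered error
   rates low by 1–2% relative, comparable to the sampling error of a
   10⁶-base run. End-to-end alignment counts every error exactly once;
   junk reads are still rejected because they cannot escape their mismatches
   by clipping. A read is `aligned=False` when its best score falls below
   `min_score_fraction · match · read_length` (default 0.30 — generous for
   indel-rich platform reads, far above anything a random read achieves
   under end-to-end alignment).
5. **Accumulation.** Reverse-strand alignments are tallied in reference
   coordinates with read bases complemented. Read-N columns are emitted as
   M by the aligner (a masked base is not an observed error), count toward
   aligned bases, and are excluded from all substitution tallies and matrix
   denominators.

## Scoring scheme

match +2, mismatch −4, gap open −6, gap extend −1; a length-k gap costs
`open + (k−1)·extend`, and an insertion run followed directly by a deletion
run re-opens. The emitted score always equals recomputation from the ops
string and the sequences. The alignment kernels are verified in the test
suite against an independent brute-force recursive scorer on hundreds of
random instances up to 50 bp.

## Substitution matrix and exclusions

The base-specific substitution matrix counts, for each reference base,
how often it is read as each other base — but only at reference positions
outside *excluded regions*, so that a few error-prone contexts cannot
dominate the base-specific picture. Excluded are homopolymer runs of
≥ `homopolymer_min_run` bases (default 4 — a four-base stretch already
measurably perturbs flow-based base calling) and any `gc_window`-base window
(default 10) with G+C fraction ≥ `gc_min_fraction` (default 0.8; no
published threshold exists, so this is a package choice, configurable in
`ExclusionPolicy`). Matrix entry (ref → read) is
100 · count / non-excluded aligned columns of that reference base; row
totals are exact off-diagonal sums. Substitutions inside excluded regions
still count toward the overall substitution rate — exclusion applies to the
matrix only. Transition rate is the mean of the four transition entries
(A↔G, C↔T); transversion rate the mean of the remaining eight.

## Simulator

The simulator generates the study conditions for closed-loop validation:
full constructs (adapter + barcode + linker + insert + linker + adapter)
drawn uniformly over the packaged panel, samples and strands, with

* substitutions as independent Bernoulli draws per template base
  (probability `subst_rate`), the replacement base drawn from a 4×4
  conditional bias matrix (rows sum to 1, zero diagonal);
* single-base indels as independent Bernoulli draws per template base
  (probability `indel_rate · homopolymer_indel_factor^(run−1)`, capped at
  0.5, where *run* is the length of the homopolymer containing the
  position); insertion vs deletion is 50/50, inserted bases uniform; longer
  indels are available behind `indel_extend_p` (geometric) but default off,
  single-base being the dominant platform mode;
* read length by a fixed-length model or a full-length-with-geometric-
  short-tail model; quality scores flat, linearly declining, or Gaussian
  noisy, clamped to [2, 40].

Independent-Bernoulli injection makes the recovery arithmetic exact: the
recovered rate is binomially distributed around the injected rate, so
"within 3 binomial standard errors at ≥ 10⁶ aligned bases" is a meaningful
acceptance band. A single seeded generator drives every draw in a fixed
order, so a run is byte-reproducible, and every injected event is logged
with template and reference coordinates; replaying the log reproduces each
read byte-for-byte (tested).

The packaged per-platform presets inject errors at the published run-level
rates (454 GS FLX: 0.07% substitutions / 0.18% indels, transition-dominant,
homopolymer factor 1.8, declining quality; IonTorrent PGM: 0.13% / 0.60%,
factor 1.6, truncated read-length tail, noisy quality around Q32; Illumina
MiSeq: 1.53% / 0.04%, transversion-heavy bias following the published
base-specific pattern, fixed 250-base reads, flat Q38). Default qualities
are ≥ 30 so the filter keeps everything unless a degraded quality model is
chosen deliberately.

The packaged reference panel is five exon-sized synthetic amplicons
(325–370 bp) named after the CREBBP exonic amplicons they emulate; the
sequences are pseudo-random stand-ins, not the real exons, but carry the
error-relevant contexts (a 7-base A run, a 13-base T run, a GC-rich
stretch). What passing tests therefore show is that the *estimator* is
correct under the stated error model; they do not certify behaviour on real
base-caller artefacts (context-dependent miscalls beyond the bias matrix,
flow-space signal effects, PCR chimeras, paired-end structure), none of
which the simulator attempts to emulate.

## Known detection limits

Parameter recovery is not perfectly lossless, by the nature of alignment:

* a deletion of the first or last covered template base is invisible
  (nothing flanks it), and indels at read ends can be absorbed as terminal
  substitutions — together ≈ 0.5–1% relative loss at 300-base reads;
* an insertion and a deletion falling in the same homopolymer run cancel
  exactly (rate ∝ indel_rate², negligible at platform rates);
* near repeats, equal-score gap placements occasionally re-gap a column
  next to substitution clusters, slightly inflating indel counts at very
  high substitution rates.

These effects are an order of magnitude below the 3-binomial-SE acceptance
band at the problem sizes used.

## Problem sizes

The acceptance script simulates 12,000 reads for the MiSeq- and PGM-level
targets and 22,000 for the 454-level target (2.2–5.8 million aligned bases
per target; each recovery is then ~15–25 standard errors wide relative to
the 10⁶-base minimum), chosen so a full run completes in a few minutes on
one core. The test-suite recovery checks use ≥ 10⁶ aligned bases each.

## Reports

`run_rates.tsv`, `amplicon_rates.tsv` and `subst_matrix.tsv` print
percentages rounded half-up to two decimals (the print precision of the
published comparison tables); `report.json` carries full-precision rates,
raw counts, stage counts and QC summaries. Outputs are byte-deterministic
for identical inputs; logs contain no timestamps.
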