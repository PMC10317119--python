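# plasmidval

Barcode-free validation of pooled plasmids sequenced on nanopore long-read
platforms.

After molecular cloning, a plasmid must be checked against its intended
sequence. Sanger sequencing covers only ~900 bp per primed reaction and
struggles with secondary structure, while short-read sequencing cannot
attribute reads inside pools of near-identical constructs. Long nanopore
reads span entire plasmids, so a pool of constructs can be sequenced in one
run *without barcodes* — provided the analysis can work out which read came
from which plasmid. `plasmidval` implements that analysis as a library and
CLI for bench scientists validating 2–100 plasmids at a time:

* **Unique-region binning ("biobin")** — scan the reference pool for
  markers (>3 bp) present in exactly one plasmid, then assign each read by
  a two-stage alignment: a *context score* against the marker ±20 bp of
  flanking sequence, then a *fine score* of the hit against the bare
  marker. Both are percent-of-maximum local alignment scores
  (100 · score / (match · target length)); a read is binned when exactly
  one reference passes both gates (context ≥ 55, fine > 80, with the
  published biobin scoring match 3, mismatch −6, gap open −10, extend −5).
* **Rotated-reference demultiplexing** — for clonal pools, each clone is
  linearised at a different restriction site; supplying one copy of the
  reference per clone with its origin rotated to that cut site makes
  full-length reads score cleanly only against their own rotation.
  Assignment requires a margin between best and second-best (banded
  semiglobal) scores, so identical non-rotated references can never claim
  reads.
* **Reference-guided consensus** — seeded, banded affine-gap alignment of
  each bin to its reference, per-column plurality voting over
  {A, C, G, T, deletion} plus polished junction insertions. Uncovered
  positions are never back-filled from the reference; low-depth columns
  become N.
* **Validation report** — consensus vs. reference global alignment
  (needle-convention scoring: match 5, mismatch −4, gap open −10, extend
  −0.5), substitution/insertion/deletion tallies, and a per-plasmid quality
  score `100 · (1 − differing bases / alignment columns)`.
* **Pool simulator** — circular plasmid pools (shared-backbone-with-marker
  or fully dissimilar), transposase-style random read starts or
  restriction-style cut-site starts, a parametric nanopore error model
  (~10% aggregate substitution/insertion/deletion with homopolymer-biased
  deletions), and injectable, optionally subclonal, variants with truth
  tables — so every stage is testable without a sequencer.

## Worked example

Simulate a three-plasmid pool (2-kb backbone, distinct 24-bp markers,
~10% read error), then corrupt one reference so it carries 22 bp that the
sequenced plasmid lacks — the classic "undetected deletion" scenario:

```bash
plasmidval simulate --n 3 --base-len 2000 --marker-len 24 \
    --reads 60 --seed 11 --outdir sim
plasmidval run --reads sim/reads.fastq --refs sim/references.fasta \
    --mode biobin --outdir out
```

Output (also written to `out/summary.tsv`):

```
   ref_id  reads  mean_depth  substitutions  insertion_bases  deletion_bases  quality_score  status                          flags
plasmid01     18        17.7              0                0               0         100.00    pass
plasmid02     17        16.7              0                0              22          98.92 flagged quality<99.5;deletion:22bp@898
plasmid03     15        14.7              0                0               0         100.00    pass
```

Reading the table: 18/17/15 of the 60 reads per plasmid passed both binning
gates (strict gates discard noisy reads rather than risk misassignment —
~17× depth is still ample for an exact consensus). Plasmids 1 and 3 match
their references base-for-base (quality 100). Plasmid 2's consensus is
missing a 22-bp block at reference position 898 — exactly the corruption we
injected — so the run exits non-zero and the row is flagged. Per-plasmid
needle-style alignments (`out/*.needle.txt`) show the gap in context, and
`out/*.sam` lets any viewer display the read pileup, including subclonal
populations that the consensus hides.

`plasmidval run --mode rotated --cut-manifest cuts.tsv` handles clonal
pools (the manifest lists `ref_id  cut_position  enzyme`), and
`--mode map-all` maps every read to its best locus across all references
for dissimilar pools without binning.

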