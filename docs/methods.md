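# Methods

This note documents the models and numerical choices behind `plasmidval`:
what each stage computes, which parameters matter, what the simulator does
and does not emulate, and where the design was genuinely open.

## Pairwise alignment core

All stages share one affine-gap aligner (three-state Gotoh recurrence) over
the alphabet {A, C, G, T, N}, with N scoring as a mismatch against
everything, including N. A gap of length k costs
`gap_open + (k−1)·gap_extend`; switching directly between an insertion and
a deletion opens a new gap event. Two scoring schemes are used:

| scheme  | match | mismatch | gap open | gap extend | used for |
|---------|------:|---------:|---------:|-----------:|----------|
| binning | 3 | −6 | −10 | −5 | context/fine marker scores, rotation margins |
| needle  | 5 | −4 | −10 | −0.5 | read→reference mapping, consensus-vs-reference reports |

Scores are doubled to integers internally so the half-point gap extension
stays exact; reported scores are rescaled. Traceback tie-breaking is
deterministic: diagonal moves are preferred over gaps and deletions over
insertions, both while filling and at the final cell, so co-optimal
alignments always resolve the same way.

Three modes are exposed: global (both sequences fully consumed), local
(Smith–Waterman, score ≥ 0, possibly empty), and semiglobal ("fitting":
the read fully aligned, reference end-gaps free). Semiglobal alignment may
be banded around a diagonal estimated from shared 13-mers (band width
`100 + 0.05·read length`, generous against the indel drift of ~10%-error
reads, whose standard deviation is ~20 bases over a 6.5-kb read); a band
that contains no path raises a distinct error so callers can retry
unbanded. Mapping uses the needle scheme because its cheap gap extension
keeps long read indels contiguous; under the binning scheme a 100-bp
insertion is cheaper to scatter into mismatch runs, which destroys pileup
insertion calling.

Normalised scores are percent-of-maximum: `100·score/(match·target_len)`,
clamped at 0, so a perfect full-length hit of the target scores 100
regardless of target length. The binning thresholds quoted below are on
this scale; the original tool's normalisation is not published, so this
definition is this package's own and is stated wherever scores surface.

## Unique regions

A marker is a substring occurring — in either orientation — in no other
reference of the pool (occurrences elsewhere in the *same* reference do not
disqualify it; binning only needs cross-reference uniqueness). Discovery
builds one generalized suffix array over both strands of every reference
(circular references doubled so markers can span the origin), computes for
every position the longest prefix shared with any *other* reference
(document-aware matching statistics via Kasai LCPs and two min-LCP sweeps),
and takes one-past-that-length as the shortest unique substring per start
(minimum marker length 4, i.e. >3 bp). Boundary effects in the combined
text can only over-estimate a matching statistic, which lengthens a
candidate but never falsely declares uniqueness.

Nested candidates are removed, the survivors merged into maximal unique
runs, and runs longer than `max_marker_len` (default 64) are tiled into
windows that each contain a complete shortest-unique substring — so every
reported marker is itself unique, while context alignment cost stays
bounded. At most `max_regions` (default 8) windows are kept per reference,
chosen spread along the plasmid rather than longest-first: for dissimilar
pools the maximal unique run is essentially the whole plasmid, and spread
markers mean the binned reads tile the full sequence instead of clustering
around one locus (which would leave coverage holes in the consensus).
Candidates longer than the cap are considered only when nothing shorter
exists anywhere on that reference.

## Two-stage binning

Stage one locally aligns the read (both orientations) against each marker's
context (marker ±20 bp flank) and normalises by context length; stage two
re-aligns the context hit against the bare marker and normalises by marker
length. A reference passes when context ≥ `context_threshold` (default 55)
and fine > `fine_threshold` (default 80); a read is assigned only when
exactly one reference passes — two or more passers mean "ambiguous", so
chimeric reads never contaminate a bin. The fine gate (>80) is the
published assignment rule; the context default of 55 is this package's
choice for a gate published only as "tunable": loose enough that a 64-bp
context hit survives ~10% read error, strict enough to reject accidental
flank-only hits. On a 24-bp marker the >80 gate admits at most one
substitution (one sub: 100·63/72 = 87.5; two: 75), which is why assignment
rates at 10% error sit near the fraction of reads whose marker copy has ≤1
error — deliberately conservative, trading yield for near-zero
misassignment.

For throughput, context alignment is seeded: it runs only inside read
windows around exact 9-mers shared with the context (per orientation), and
a reference's regions are tried longest-first with early exit once one
passes both gates. Seeding can only lose candidate hits (measured effect:
a few percent of true hits at 10% error, none at low error), never create
them; `prescreen_k=0` restores exhaustive full-read alignment, and a test
pins the two paths to identical assignments on clean reads.

## Rotated-reference demultiplexing

Clones cut at different restriction sites are told apart by supplying one
reference copy per clone, rewritten to start at that clone's cut site.
Reads are never rotated; references are. Each read is scored (seeded,
banded semiglobal, both orientations) against every rotation and assigned
to the best iff `best − second ≥ margin_pct%` of the read's maximum
possible score (default 5%, binning scheme ⇒ 0.15 per base). A mismatched
rotation forces at least the cut-separation distance of the read to align
as gaps or mismatches, collapsing its score by far more than the margin
for separations ≥ ~100 bp; identical non-rotated copies tie exactly and
assign nothing. The margin rule is score-based rather than "unique best"
to stay robust for near-full-length reads; it is this package's substitute
for an unspecified upstream mapping-quality rule, so real-run unique-read
counts are not comparable figures.

## Reference-guided consensus

Reads are mapped by seeded banded semiglobal alignment (circular references
doubled, coordinates projected modulo length so origin-spanning reads stay
contiguous), kept when identity ≥ 70% and the seeding locus is unique
(top diagonal strictly out-votes the best alternative further than a band
away) — the stand-in for a mapping-quality filter in a bespoke aligner.
The pileup counts {A, C, G, T, deletion} per column and records inserted
sequences per junction together with junction-spanning coverage.

Calling is per-column plurality. Ties resolve to the reference base when it
is among the tied symbols, else to the lexicographically smallest — a
deterministic, conservative rule. Columns with depth < `min_depth`
(default 5) become N; uncovered runs at the extremities are trimmed, never
filled from the reference, so the consensus contains no base the reads did
not support. At junctions where more than `ins_frac` (default 0.5) of
spanning reads carry an insertion, the observed inserted sequences are
polished — medoid by total alignment score, then one round of per-column
voting of all observations against it, junction insertions at the medoid
boundaries included (the medoid may be missing its first or last base) —
and the polished insert is emitted. This plurality caller replaces a neural
polisher while preserving its external contract (reference-guided, no
back-fill); per-base error profiles necessarily differ from that tool's.
Homopolymer errors are not specially corrected: gaps at homopolymer runs
are an accepted error mode at low depth.

## Report and quality score

The consensus is globally aligned to its reference under the needle scheme.
Each maximal gap run is one event; the per-plasmid quality score is
`100·(1 − (substitutions + inserted bases + deleted bases)/alignment
columns)`, floored at 0 — 100 exactly iff consensus equals reference.
The exact formula behind the original tool's score is not published; this
per-column difference fraction is declared as this package's definition.
Substitution and gap tallies are reported separately so either reading of
"gaps" (indel bases only, or all differing bases) is recoverable. A
plasmid is flagged (never dropped) when quality < 99.5 or any single indel
is ≥ 10 bp; both thresholds are report-level conveniences and CLI-tunable.
SAM output for circular references is written against the doubled
reference (`name::doubled`, LN = 2L) so origin-spanning alignments remain
single lines for viewers.

## Simulator

The simulator emulates pooled nanopore plasmid libraries well enough to
exercise every pipeline stage:

* **Pools** — either one random backbone (GC ≈ 0.5) with a distinct random
  marker inserted at a fixed locus per plasmid (the highly-similar-pool
  scenario) or fully random dissimilar plasmids; all circular.
* **Preparation** — `random` start mode draws uniform start positions on
  the circle (transposase preparation); `cut_site` mode starts every read
  at the plasmid's restriction site minus exponential end trims (mean
  20 bp), yielding near-full-length cut-to-cut reads.
* **Lengths** — lognormal (μ = 8.34, σ = 0.6 on the log scale, giving a
  length-weighted median — N50 — near 6 kb), truncated at template length;
  plasmid-sized templates therefore yield mostly full-length reads.
* **Errors** — independent per-base substitution/insertion/deletion draws,
  defaults 0.04/0.03/0.03 (~10% aggregate, the commonly quoted nanopore
  error rate), with the deletion rate multiplied by 2 inside homopolymer
  runs ≥ 4 — the dominant nanopore error mode. Qualities are constant at
  the Phred equivalent of the aggregate error rate (Q10 at defaults),
  the simplest model consistent with mean-error-probability filtering.
* **Variants** — insertions, deletions and substitutions with truth
  records, optionally subclonal: each read draws the variant haplotype
  with probability `subclonal_fraction`.
* **Determinism** — one integer seed; identical inputs give byte-identical
  FASTQ and truth tables.

What it does *not* emulate: basecaller-specific quality profiles and
error autocorrelation, chimeric reads, adapter sequence, pore-dependent
length biases. Passing tests therefore demonstrate the pipeline's logic
under a realistic error *rate* and structure, not performance on any
particular instrument's quirks.

## Problem sizes used in the shipped checks

The automated checks run desk-scale versions of the study designs: a
16-plasmid shared-backbone pool at 200 reads per plasmid for the
misassignment bound (<6% among assigned reads; measured ≈0% because the
fine gate on a 24-bp marker admits ≈1 substitution at most); 10 dissimilar
2.5-kb plasmids at 100 error-free reads each for the exact round trip;
1/10/100-bp indel recovery at 100 reads and 10% error; and a three-rotation
6.5-kb clone pool with closest cuts 579 bp apart. These sizes keep a full
run in minutes on one CPU while preserving each effect being measured.

## Known limitations

* Very large rearrangements (multi-kb indels, inversions) are outside the
  reference-guided model; they surface as unmappable reads or collapsed
  scores, not as called variants.
* Subclonal variation is visible in the emitted SAM but, by design, never
  in the consensus (the majority allele wins).
* The binning gates discard a large fraction of 10%-error reads on short
  markers; with ≤6-bp markers assignment is effectively limited to reads
  carrying an error-free marker copy, and consensus quality degrades with
  the small bins (mirrored in the marker-length trend test).
* The uniqueness scan is exact for pools up to ~100 plasmids of ordinary
  size; it is not meant for genome-scale references.
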