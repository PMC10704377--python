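# Methods

## The measurement being modelled

Sodium bisulfite deaminates cytosine to uracil efficiently only in
single-stranded DNA. Applied under non-denaturing conditions to genomic
or plasmid DNA, it therefore marks whatever was single-stranded at
treatment time: the displaced strand of an R-loop, or the strand
opposite a folded G-quadruplex. After PCR amplification, TA cloning and
Sanger sequencing, each clone represents one original molecule. A clone
derived from the top strand shows conversions as C→T at reference-C
positions; a clone derived from the bottom strand — whose cytosines sit
opposite top-strand guanines — shows them as G→A when read in
top-strand coordinates. The package operates entirely in top-strand,
0-based, half-open coordinates; 1-based positions appear only in
human-readable report formats (VCF-like output).

## Clone processing

**Alignment.** Clones are aligned globally to the reference amplicon
with biopython's `PairwiseAligner` under a bisulfite-aware asymmetric
substitution matrix: match +1, mismatch −1, but ref-C/clone-T and
ref-G/clone-A score as matches, so conversion density cannot distort
gap placement. Affine gaps (open −4, extend −1). Alignment identity is
measured only over substitution columns that carry identity information
(i.e. excluding the two bisulfite-ambiguous pairs); clones below an
identity floor of 0.9 are rejected, and a run in which more than half
the clones are rejected aborts with a data error, since that pattern
indicates the wrong amplicon rather than bad clones.

**Strand of origin.** C→T columns vote for top-strand origin, G→A
columns for bottom-strand. The majority wins with score =
majority/total; a clone is `undetermined` when fewer than 3
conversion-like mismatches exist or the majority score is below 0.8.
These two thresholds are operational choices (the underlying assay
leaves strand assignment implicit); on simulated clones with ≥5 true
conversions, assignment accuracy exceeds 99% (see
`scripts/acceptance.py`).

**Conversion calls.** At each informative position (reference C for
top-strand clones, G for bottom-strand) the call is `converted`
(bisulfite-expected base), `unconverted` (reference base),
`mismatch_other` (any other base; counted as unconverted for stretch
purposes and tallied for QC — clones with >5% such calls are flagged),
or `excluded` (alignment gap). CpG context is flagged from the
reference; CpG is palindromic, so a bottom-strand informative position
`i` is CpG context iff the reference reads C at `i−1`.

**CpG handling.** 5-methylcytosine resists bisulfite whether
single-stranded or not, so CpG sites are ambiguous: an unconverted CpG
may be methylated, and a converted CpG is only trustworthy when its
neighbourhood shows it sat inside a single-stranded region. The rule
applied: a converted CpG keeps its status only when the `cpg_run_k`
informative non-CpG calls immediately preceding it are all converted;
otherwise it is reclassified `excluded`. "Preceding" is taken along the
molecule's own 5′→3′ direction — ascending top coordinates for
top-strand clones, descending for bottom-strand clones — since the
certifying run should lie on the same molecule upstream of the site as
read. The default `cpg_run_k` is 4, with 2 available via configuration:
the assay literature states both values in different places, and the
package exposes the discrepancy rather than hiding it. The rule never
touches non-CpG calls and is idempotent.

## Stretch detection and clone classification

Two notions of a conversion stretch are computed, both counted in
informative cytosines (not nucleotides; the nt span of every stretch is
reported separately, since a "13-cytosine" run typically covers 50–65
nt of sequence):

- **Continuous**: maximal runs of ≥ `min_run` consecutive converted
  calls. Any non-converted call — including `excluded` — breaks a run:
  an indel or ambiguous column is not evidence of conversion.
- **Windowed**: with `excluded` calls skipped (ambiguity should not
  mimic unconverted cytosines either), any window of `window`
  consecutive usable calls containing ≥ `min_in_window` conversions
  qualifies; overlapping qualifying windows merge. Defaults 12-of-15.
  The window slides over every position; a fixed partition would make
  detection depend on an arbitrary phase.

Clones are classified into the categories used for condition
comparisons: `run_gt15` (a continuous run of >15), `run_gt10` (>10),
`windowed_only`, or `none`; condition tables report cumulative counts
(a clone with a 17-run counts in both >10 and >15) and true zeros.

## Footprint calling

Per-position conversion frequency is computed per strand (top- and
bottom-strand clones read different cytosines and are never pooled):
fraction = converted / covered, where `excluded` calls reduce coverage.
Positions with fraction ≥ `min_fraction` (default 0.5) merge into
intervals, bridging gaps of ≤ `max_gap_nt` between consecutive
qualifying positions; intervals spanning < `min_span_nt` (default 30
nt) are dropped. A clone supports a footprint when at least half of its
covered informative calls inside the interval are converted.

`max_gap_nt` defaults to 20 nt. The gap tolerance must cover two kinds
of evidence gaps interior to real footprints: stretches of sequence
without informative cytosines, and CpG sites whose converted calls the
CpG rule reclassified as excluded — the latter regularly produce 15–20
nt gaps flanked by fully converted positions. 20 nt bridges these while
remaining below `min_span_nt`, so two independently qualifying
footprints can never be merged through a sub-threshold interval.
Footprints at the shortest end of the biologically reported range
(~30 nt) sit at the detection limit under these defaults: the first and
last informative cytosines inside a 30 nt region usually span less than
30 nt. Detecting them requires lowering `min_span_nt`, at the cost of
background susceptibility.

## Motif scanning

**WRC.** All occurrences of W R C (W = A/T, R = A/G), overlapping hits
included; minus-strand occurrences are reported as G Y W (Y = C/T) in
plus coordinates. Region summaries report both-strand and plus-only
counts side by side, since published hotspot counts rarely state which
convention they use.

**G-quadruplex.** The conventional motif is four G-tracts of ≥3 G
separated by loops of 1–7 nt. The extended definition adds two
deviations with experimental support that regex-style predictors miss:
at most one long loop (up to 21 nt, the range over which a loop can
fold back as a duplex hairpin), and at most one bulged tract of the
form G+NG+ — a single non-G interruption — whose total G count still
meets the tract minimum. Reporting is greedy and non-overlapping: the
scan takes the leftmost position where any valid tract/loop
decomposition starts, reports the maximal hit there, and resumes after
its end. Because several decompositions can share a start, a canonical
tie-break makes the output deterministic: maximal final end, then per
tract in order (maximal end, pure preferred over bulged, maximal
start). The scanner finds maximal ends by memoized search;
`g4_brute_force` enumerates all 4-tract decompositions independently
and applies the same tie-break, and the test suite asserts exact
agreement on short strings. `g4_match_spans` enumerates every span
admitting a valid decomposition, which is how the
conventional-is-a-subset-of-extended property is stated and tested:
greedy *reports* of the two configurations legitimately differ (a long
loop can extend a hit across what the conventional scan reports
separately), but every conventional match span is an extended match
span.

**Composition.** GC content in percent; GC skew (G−C)/(G+C) per
sliding window (NaN where a window has no G or C).

## Mutation analysis

AID deaminates cytosines in single-stranded DNA; replication fixes the
uracil as C→T (or G→A for bottom-strand events), while aberrant
base-excision repair of the uracil can yield any substitution.
`call_mutations` emits one record per substitution column of the
bisulfite-aware alignment; in bisulfite-treated material C→T/G→A can be
suppressed as conversions rather than mutations. Substitutions within
2 nt of an alignment gap are excluded as indel artifacts and tallied.
Mutation frequency is mutations per total nucleotide sequenced, where
the denominator counts aligned non-gap clone nucleotides (the most
direct reading of "total nucleotide sequenced"; amplicon length ×
clones is available by passing that number explicitly). Two-condition
comparisons report 100 × (f_A − f_B)/f_A. Motif annotation flags
records inside a hit span or within a 5 nt flank.

## Synthetic data

The simulator emulates the study design the analyses were built for:

- a reference locus of i.i.d. bases at 57% GC (the GC content of the
  breakpoint locus that motivated the design), with optional planted
  G4 motifs;
- planted strand-specific footprints: conversion probability `p_ss`
  (default 0.95) per informative cytosine inside a same-strand
  footprint, `p_bg` (default 0.02) elsewhere. Strand specificity
  encodes the central asymmetry observation — a bottom-strand footprint
  produces no excess conversion in top-strand clones;
- inside footprint intervals the base composition is skewed so the
  footprint strand's informative cytosines occur at density 0.4
  (`footprint_informative_density`): R-loops form over G-skewed
  regions, and the displaced-strand read-out is correspondingly dense.
  Planting a footprint over unskewed sequence would not resemble one;
- per-base sequencing error (default 0.001) substituting uniformly
  among the three alternatives — occasionally mimicking conversion,
  which is desired realism;
- AID mode: deamination at a given rate per exposed C/G inside supplied
  single-stranded intervals, with an optional misrepair fraction
  turning an event into a random other substitution;
- clone strands drawn by `strand_mix`; decisions independent per clone
  (no PCR lineage structure, no duplicate clones, no quality scores).

All randomness flows from one integer seed through a single numpy
generator; outputs are byte-identical across runs and platforms. Truth
tables record every conversion and mutation decision and round-trip
losslessly through TSV.

What passing tests on this generator do **not** show about real data:
PCR duplicates and chimeras are absent (clone counts are effectively
independent draws), conversion efficiency is uniform rather than
sequence-dependent, CpG methylation is not itself simulated (the CpG
rule is exercised through the rule's own exclusions rather than through
planted methylation), and real single-strandedness is heterogeneous
across molecules rather than a fixed interval.

## Problem sizes and numerics

The shipped checks use a 600 nt locus with a 60 nt planted footprint
and 50 clones (20 seeds) for footprint recovery; 1,000 clones on a
400 nt locus for strand-assignment accuracy; 25 clones × 500 nt
(12,500 nt sequenced) for deamination-rate recovery; 1,000 random call
strings (≤60 calls) and 120 random G-rich strings (≤40 nt) for the
oracle-equivalence checks, with 1,000 strings (≤120 nt) for the
match-span inclusion property. These sizes give stable statistics
(binomial 3σ bands) at interactive runtimes. Undefined quantities
(frequency at uncovered positions, skew without G/C, summaries of
uncovered regions) are NaN sentinels, never zeros. Breakpoint
clustering joins positions at gap ≤ threshold (boundary gap joins);
the default 200 nt threshold is an operational choice for locus-scale
breakpoint lists, configurable throughout.
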