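# bisfoot

Single-molecule bisulfite footprinting of single-stranded DNA.

Non-denaturing sodium bisulfite deaminates cytosine to uracil only where
the DNA is single-stranded. After PCR, cloning and Sanger sequencing,
each clone is a single molecule in which converted cytosines read as
C→T (for molecules derived from the top strand) or as G→A in top-strand
coordinates (for bottom-strand molecules). Dense runs of conversions in
one clone therefore map single-stranded regions — R-loops and strands
displaced by G-quadruplexes — at single-molecule resolution. `bisfoot`
implements this analysis for locus-scale studies of genome fragility
(e.g. translocation breakpoint clusters), together with the motif and
mutation analyses that usually accompany it:

- **Bisulfite footprinting** — bisulfite-aware clone alignment,
  strand-of-origin assignment, per-cytosine conversion calling with CpG
  handling, conversion-stretch detection (continuous runs such as >10 or
  >15 conversions, and dense windows such as 12-of-15), per-position
  conversion frequency, and footprint-interval calling.
- **Motif scanning** — AID hotspot motifs WRC (W = A/T, R = A/G; the
  reverse-complement GYW reported on the minus strand), conventional
  G-quadruplex motifs G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, and extended motifs
  allowing one long (hairpin-forming) loop and one bulged G+NG+ tract;
  GC content and sliding-window GC skew (G−C)/(G+C).
- **AID mutation analysis** — substitution calling against a reference,
  mutation frequency as mutations per total nucleotide sequenced,
  per-class spectra, motif annotation, and two-condition comparisons
  (e.g. ±RNase H percent reduction).
- **Region utilities** — anchor-offset region construction,
  single-linkage breakpoint clustering, bedGraph/wiggle signal-track
  summarisation over regions.
- **Synthetic data** — a fully seeded clone simulator that plants
  single-stranded footprints and AID deamination with complete ground
  truth, so every pipeline stage is testable without sequencing data.

## Worked example

Simulate 50 bottom-strand clones over a 600 nt locus with one planted
bottom-strand footprint at [200, 260), then call footprints:

```bash
cat > sim.yaml <<EOF
ref_length: 600
footprints: [[bottom, 200, 260]]
p_ss: 0.9
p_bg: 0.02
n_clones: 50
strand_mix: 1.0
seed: 11
EOF
bisfoot simulate --config sim.yaml --out fixture
bisfoot footprint --ref fixture/reference.fasta \
                  --clones fixture/clones.fasta --out fp
cat fp/footprints.bed
```

```
ref	209	260	footprint_bottom_0	864	-
```

One footprint is called on the bottom strand spanning [209, 260) —
within 9 nt of the planted truth — with a BED score of 864, i.e. a mean
conversion fraction of 0.864 across the interval (86% of covered
informative cytosines converted, against a 2% background elsewhere).
`fp/summary.tsv` shows all 50 clones assigned to the bottom strand and
77 per-clone conversion stretches supporting the call:

```
strand	n_clones	n_footprints	n_stretches
top	0	0	0
bottom	50	1	77
```

Scanning the same reference for motifs:

```bash
bisfoot scan --ref fixture/reference.fasta --out scan
cat scan/scan_summary.tsv
```

```
region	start	end	n_wrc_both	n_wrc_plus	n_g4_conventional	n_g4_extended	gc_content
whole	0	600	78	36	0	0	56.166666666666664
```

The 600 nt locus carries 78 WRC/GYW AID hotspots over both strands and
no G-quadruplex motif (none was planted), at 56.2% GC.

Library use mirrors the CLI: `bisfoot.simulate` generates clone sets,
`bisfoot.pipeline.run_footprint` returns per-strand profiles,
frequency tables and `FootprintCall` objects, and `bisfoot.motifs` /
`bisfoot.mutations` expose the scanners and mutation statistics.

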