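# Methods

## Model

The pipeline treats a small-RNA sequencing experiment as a set of *tags*
(distinct sequences) with *read counts* (how many times each tag was cloned
and sequenced). Its central assumption is that stable ncRNAs — even ones
longer than the 18–32 nt size fraction — leave a footprint of contiguously
overlapping tags across their full length, so a cluster of overlapping
placements (a tag-contig, TC) is evidence for a transcript, and the maximal
per-base accumulation of read weight (tag-depth) is a proxy for its
expression level. Candidate classes are then separable by the joint
distribution of TC length, tag-depth, genomic context and signature motifs:
box H/ACA snoRNAs are long (120–180 nt in *Drosophila*), intronic and sense
to their host gene, with ANANNA in the hinge and ACA near the 3′ end; box
C/D snoRNAs are 60–100 nt, intronic (sense) or intergenic, with RUGAUGA /
CUGA near their ends; transposon-derived signal is double-stranded and is
removed by strand competition rather than by sequence homology.

Multi-mapping is handled by even division: a tag with *r* reads and *n*
placements contributes *r/n* per placement, and tags with *n > r* are
discarded outright — their per-locus evidence is below one read and mostly
reflects repeats. Division happens after dropping placements on excluded
chromosomes (`chrM`, `chrU`, `chrUextra`); counting excluded hits would
dilute the weights of every retained locus for no benefit, since those hits
are never reported.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `strand_ratio_min` | 10 | minimum tag-depth fold-advantage over the deepest overlapping opposite-strand TC (inclusive) |
| `haca_len` / `haca_depth_min` | 120–180 nt / 15 | box H/ACA candidate window (length bounds inclusive) |
| `cd_len` / `cd_depth_min` | 60–100 nt / 6 | box C/D candidate window |
| `group_depth_min` | 100 | depth floor for unclassified group banding |
| `group1_depth_min` | 1000 | group 1 depth floor |
| `short_len_max` | 40 nt | strict upper bound for "short" groups 1/2 |
| box C / box D | RTGATGA / CTGA, ≤ 1 mismatch, ±10 bp of 5′ / 3′ end | anchored snoRNA motifs (DNA alphabet) |
| box H / ACA | ANANNA / ACA, exact, ±20 bp of midpoint / 3′ end | ANANNA already has three free positions, so no mismatch budget |
| 20% rule | 0.20 | minimum fraction of the TC length overlapping a feature class |
| conservation | ≥ 15 bp | minimum single-element overlap with a conserved element |

The length windows and depth floors are the observed ranges of TCs covering
full-length annotated snoRNAs of each class; the 10× ratio reflects the
strong sense bias of ncRNA-derived TCs versus the balanced strandedness of
transposon-derived ones.

## Numerical and design choices

- **Coordinates** are 0-based half-open everywhere; a locus name
  `chrN_start_end` has length end − start. GFF3 is converted on read.
- **Weights and depths are reals**; no rounding anywhere in the cascade
  (rounding would break read-mass conservation, which tests assert to
  1e-9). Threshold comparisons use ≥ on the real value.
- **Depth computation** runs on coordinate-compressed segments between
  placement endpoints, summing member weights in a fixed (start, end, id)
  order, which makes it bit-identical to a literal per-base accumulation —
  the equivalence the oracle tests assert exactly, not approximately.
- **Assembly** merges placements overlapping by ≥ 1 nt; abutting placements
  do not merge. Nearby-but-non-overlapping TCs are never merged (that
  heuristic conflates adjacent snoRNAs).
- **Group bands** partition the depth axis: group 2 is 100 ≤ depth < 1000,
  so fractional depths (e.g. 999.5) cannot fall between group 2 and
  group 1.
- **The 10× filter is inclusive** (retained at exactly 10×) and is taken
  against the *maximum* opposing depth.
- **Motif windows are start-based**: a hit qualifies when its start lies
  within the window of the anchor (the start the motif would have flush
  with the TC end, or centred on the midpoint). Among qualifying hits the
  best has fewest mismatches, then smallest anchor distance, then smallest
  offset — fully deterministic. Flanks extend into the genome because TCs
  can slightly under- or over-run the mature RNA; box C must precede box D
  (and H precede ACA) in the TC frame, as the biology requires.
- **Conservation is per element**: one element must overlap by ≥ 15 bp;
  two elements contributing 8 bp each do not qualify (`min_overlap` is a
  parameter).
- **Coverage report** counts same-strand TCs only, and percentages render
  with half-up rounding to one decimal. Classes with zero annotated loci
  render `N/A`.
- **Context priority** is annotated ncRNA > exonic > repeat > intronic >
  intergenic, each gated at the 20% rule; a TC with ≥ 20% gene-span overlap
  is never intergenic (genic-but-not-exonic resolves to intronic, sense
  when the TC strand matches the host gene).
- **Sequential exclusion**: the C/D window runs on TCs not consumed by the
  H/ACA window; group banding runs on TCs not called as snoRNAs, so every
  TC gets at most one call. H/ACA-windowed TCs that fail the motif test are
  emitted as an `snRNA_like` sidecar for manual follow-up (identifying
  snRNAs proper needs homology evidence, which is out of scope); an
  exclusion-id hook stands in for homology-based transposon removal before
  group banding.

## Synthetic data

`synthetic_data.generate_fixture` emulates the tag-generation process on a
desk-scale genome (default 200 kb plus a 2 kb `chrM` carrying a decoy copy
of one locus, to exercise chromosome exclusion). Eight genes
(exon–intron–exon–intron–exon, alternating strands) provide intronic and
intergenic slots. Planted loci carry the correct motif grammar; defaults
plant three box C/D loci (74/81/69 nt at depths 566/42/993), two box H/ACA
loci (145/143 nt at 105/234), one 21-nt locus at depth ≈ 5000 containing
the GC-rich 18mer consensus GTCCACCCGGGGGCGCCA, a 200-nt transposon-like
region emitting tags from both strands at a 2:1 depth ratio (well inside
10×, so the strand filter must remove it), and annotated tRNA-like and
miRNA-like loci for the coverage report — lengths and depths mirroring
experimentally validated candidates of each class. Tags tile each planted
locus as overlapping windows whose first/last windows pin the TC boundary
exactly, with per-tag counts scaled to reach the target depth; 300
background tags at depth 1 are sampled away from planted loci; about half
of planted ncRNAs also emit one full-length (precursor-like) tag.

What the generator does **not** emulate: sequencing error, 5′/3′-end
processing biases of snoRNA-derived small RNAs, realistic repeat families
(the decoy is a single region, not a dispersed element), chromatin- or
stage-specific expression, and non-uniform base composition. Passing
recovery tests therefore shows the cascade's logic is correct under its own
model of the data, not that the thresholds are optimal on real libraries.

## Problem sizes

Tests and the acceptance script run the full cascade on the 200 kb default
fixture (≈ 375 tags, ≈ 300 TCs, seconds on one CPU); assembly/depth
equivalence is checked on 500 random interval sets against per-base
oracles, and k-mer scan equivalence on a random 100 kb genome at k = 18
with 0–2 mismatches against an all-windows Hamming scan. The built-in exact
matcher (a per-length window hash) is intended for genomes up to ~100 Mb;
for larger genomes, import pre-mapped placements from BED.

## Known limitations

- Exact matching only; no mismatch-tolerant or clipped alignment.
- No secondary-structure validation of snoRNA candidates and no
  homology-based annotation; candidate lists are meant for downstream
  screening.
- The strand filter needs opposite-strand signal to act; single-stranded
  repeats pass it and must be caught via the exclusion-id hook.
- Table 2-style coverage uses same-strand TCs only; antisense-derived
  coverage of annotated ncRNAs is not reported.
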