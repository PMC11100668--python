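# Methods

## Locus model and coordinate conventions

All coordinates are 0-based half-open; 1-based coordinates appear only inside
SAM and GFF records. Strands are named by function — *cDNA-sense* (the
first-strand cDNA, and the neo mRNA transcribed from the duplex) and
*ncRNA-sense* — rather than by figure-relative "top/bottom", which is
layout-dependent and ambiguous for user-supplied loci.

A `LocusModel` stores the ncRNA 5′→3′ with the template region `[ts, te)`.
The RT reads the template RNA 3′→5′, so the *last-read* trinucleotide — the
one templating the nascent cDNA's 3′-terminal 5′-TGT-3′ — sits at the RNA 5′
edge of the template (`[ts, ts+3)`, ACA-1). The homologous ACA-2 sits at
`[te+1, te+4)` inside SL2, one base beyond the template, so that after the
jump the RT copies exactly one extra base (the complement of `ncrna[te]`)
before re-entering the template. This is the only arrangement in which
continued 3′→5′ synthesis reproduces a head-to-tail concatemer with a single
inserted junction nucleotide, and it makes the junction base a *designed*
property of the locus rather than a free parameter. The single-repeat cDNA is
modeled as *T* nt with period *T + 1*; period-based counting treats an
*n*-repeat molecule as *n − 1* junction-inclusive periods plus a terminal
*T*-nt repeat.

Stem-loop intervals SL1–SL8 are annotations locating the motifs (SL2 holds
ACA-2; SL3–SL5 fall inside the template; SL6–SL8 in the 3′ scaffold); no RNA
secondary structure is folded or checked. Phage induction is a binary
`first_strand → duplex` state switch; the polymerase performing second-strand
synthesis is not modeled, only its product (the reverse complement on the
first-strand coordinate system).

## Designed loci

`build_locus` can design a template de novo under constraints. The period
unit (unit + junction base) is sampled uniformly over A/C/G/T and repaired:

* the unit must end in the reverse complement of the jump motif (TGT for ACA);
* if a *designed frame* is requested, stop codons (TAA/TAG/TGA) in that
  circular frame are replaced by random sense codons until none remain, and
  candidates are rejected unless **every other frame retains at least one
  stop** — so a designed locus has exactly one stop-free frame, mirroring the
  one-in-three situation of a natural neo locus;
* by default a designed locus also carries a planted AGGAGG hexamer with a
  7-nt spacer before an in-frame ATG, and exact-consensus TTGACA/TATAAT
  elements laid across the junction. Placements are chosen so the motifs'
  internal TGA/TAA triplets cannot fall in the designed frame; attempts whose
  random context creates an unrepairable stop are simply resampled.

Designing a frame requires the period to be a multiple of 3; requesting one
for, say, a 118-nt template raises an error naming the constraint. With a
user-supplied template, constraints are verified rather than designed, and
the junction base is chosen (or validated) to keep the requested frame
stop-free. All generation is reproducible from an explicit seed; there is no
global random state anywhere in the package.

## Read simulation

Long-platform reads cover whole molecules end-to-end; short-platform reads
are fixed-length substrings with uniform start offsets, clipped to molecule
bounds. Reads from first-strand molecules are always emitted cDNA-sense — a
single-stranded molecule exposes only one strand to a strand-aware library —
while duplex molecules are read from either strand with probability 1/2.
Errors follow a per-base model at substitutions:insertions:deletions =
2:1:1 of the requested total rate (a deliberately simple, documented model;
it reproduces the requested per-base rate within 3 standard errors over a
read set but does not emulate platform-specific homopolymer or quality-decay
behavior). Every read appears exactly once in a truth table
(`read_id, molecule_id, true_n_repeats, strand, start_offset, error_rate,
seed`).

What the simulator does *not* emulate: phage/host kinetics, immunoprecipitation
enrichment biases, library PCR duplicates, coverage unevenness, basecaller
artifacts. Passing tests therefore demonstrate correctness of the callers'
logic under the stated generative model, not performance on any particular
instrument's error profile.

## Junction calling

A built-in fallback aligner (leftmost-longest exact match, remainder
soft-clipped, minimum seed 15 nt) keeps simulations self-contained; real data
enters as SAM/BAM with standard CIGAR semantics. Soft-clip sides are
reference-oriented ("3prime" = downstream of the aligned block on the
cDNA-sense reference), which is also correct for reverse-strand records since
SAM stores SEQ reference-oriented.

`remap_clips` models a 3′ clip as 0–3 inserted bases followed by re-entry
into the unit, scores all (mismatches, insertion, offset) placements of a
20-nt probe prefix by sliding Hamming comparison, and picks the fewest
mismatches, then the shortest insertion, then the offset closest to the cDNA
5′ start (the biologically expected jump target), flagging remaining ties as
ambiguous. A call is *expected* iff the clip lands at offset 0 with exactly
the locus junction base inserted and the anchor at the cDNA 3′ end.
Unmappable clips are returned as data, not errors. Defaults: `min_clip = 10`,
`k_flank = 10`, `max_mismatch = 0` — the published analyses state no
clip-length or mismatch thresholds, so these are this package's decisions,
chosen to make junction definitions exact on simulated data.

Junction-spanning counting is exact k-mer context matching (last `k_flank`
nt of the unit + junction base + first `k_flank` nt), per strand, normalized
as counts per million reads; occurrences (not reads) are counted so a
three-repeat read contributes two. Modal cDNA end calling uses clip-aware
alignment starts/ends with ties broken toward the smaller coordinate (both
modes kept in diagnostics).

## Repeat counting

`count_repeats` tiles a read with approximate occurrences of one
junction-inclusive period unit using edlib: an infix (HW) anchor at the
best-scoring occurrence, then stepwise prefix-anchored (SHW) extension in
both directions, with one-window resynchronization after a rejected segment.
A segment counts as a full unit iff its edit distance to the unit is ≤
`max_edit_frac · len(unit)`; matched leading/trailing remainders are reported
as `terminal_partial_fraction` and never rounded up into the count. The
orientation (read vs. reverse complement) with more accepted units wins.
Defaults: `max_edit_frac = 0.15` for long reads, 0.05 recommended for short.

One consequence worth stating: a full-length *n*-repeat molecule is
(*n* − 1) full periods plus a terminal *T*-nt repeat (edit distance 1 from
the *T* + 1 unit). At the default 0.15 budget that terminal repeat is
accepted as a full unit, so error-free reads recover exactly *n*; at
`max_edit_frac = 0` it is reported as a (*T*/*P*) partial instead. Histogram
CPM uses all reads in the sample as denominator, excludes zero-unit reads
from bins, and applies log10 with no pseudocount (empty bins are absent).

## neo detection

Circular scans operate on doubled (or tripled, for upstream windows)
sequences with hits canonicalized to `[0, period)`. For unit lengths
divisible by 3, frame *f* is stop-free iff one period read from offset *f*
contains no stop; otherwise the reading phase drifts each repeat, so a
persistent frame exists only if *no* circular position starts a stop (then
all three frames survive). Translation uses the bacterial genetic code
(table 11). Start codons default to {ATG, GTG} — GTG because a non-canonical
GUG start retains partial function in this system — with TTG available
behind a flag. The RBS model is a transparent hexamer match count to AGGAGG
over a circular 5–13-nt upstream spacer window, threshold ≥ 4; no
free-energy model is attempted. The promoter model is consensus
TTGACA/TATAAT with ≤ 2 mismatches each and a 15–19-nt spacer, and only pairs
whose footprint crosses the junction are reported. These motif parameters
are consensus-based, configurable defaults — not measured values for any
particular locus.

`scan_homolog` applies the checks in order — jump homology (ACA-1 = ACA-2
candidate), period ≡ 0 (mod 3), ≥ 1 stop-free circular frame, an in-frame
start, RBS score ≥ threshold — and reports *all* failing reasons. The
junction base is unknowable from a template alone, so if not supplied each
base is tried (A, C, G, T) and the first yielding a stop-free frame is kept;
callers with annotated loci should pass the known base. Promoter hits are
reported on accepted models but are deliberately not a rejection criterion.
Insertion-length effects use the closed form
`preserved ⟺ (period + L) ≡ 0 (mod 3)`.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on simulated data at desk
scale: junction round-trips over 100 random loci (template lengths 30–150),
stop-scan equivalence against brute-force 10-repeat translation over 1,000
random units, 500 error-free long reads spanning repeat counts 1–40, and 200
reads at 8% simulated error for the ±1 robustness check. These sizes give
stable, seed-reproducible statistics while completing in seconds. Ties are
always broken deterministically (smaller coordinate / 5′-most offset /
forward orientation), and every stochastic entry point takes an explicit
seed.

## Known limitations

* The junction caller inspects only the first junction downstream of an
  alignment anchor per read; per-molecule junction heterogeneity beyond the
  first junction is visible only across reads.
* `unit_boundaries` is guaranteed contiguous (count = boundaries − 1) only
  when no resynchronization event occurred; `n_resync` records exceptions.
* The homolog scanner takes template coordinates as given; discovering
  ncRNAs in genomes (covariance models, phylogenetics) is out of scope, as
  are differential-enrichment statistics, RNA folding, and protein structure
  prediction.
* Aberrant-jump simulation (`aberrant_jump_prob`) randomizes landing sites
  uniformly; real jump-fidelity mutants presumably have structured biases.
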