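# Methods

## Background and model

Spliced-leader (SL) trans-splicing replaces the 5′ end of a pre-mRNA with
a short leader donated by a dedicated SL RNA. Two observable consequences
drive everything in this package:

* On transcript-to-genome alignments, the retained leader fragment cannot
  align at the acceptor locus and appears as a **leading soft-clip**
  (CIGAR `S` at the query 5′ end, accounting for strand).
* The 5′ ends of SL-trimmed reads pile up at the **trans-splice acceptor
  site**, exactly as 3′-tag read ends pile up at **polyadenylation
  sites**. These pile-ups are usable as gene-boundary evidence, and an SL
  peak *inside* a locus marks a polycistron or run-through model that
  should be split.

The canonical SL RNA gene is the leader followed by a splice-donor
dinucleotide, a stem-loop region, and an Sm-protein binding site; the
locus search therefore scores each near-exact genomic SL match for a
downstream Sm-like motif and hairpin-forming potential.

## Procedures and numerical choices

**Prefix extraction.** One primary alignment per transcript: longest
reference span, ties to the leftmost coordinate (multi-mapper policy;
deterministic). Leading clips of 10–50 nt (defaults `min_clip`,
`max_clip`) are taken in transcript orientation.

**Consensus reconstruction.** Soft-clipped SL remnants share their 3′
(junction) end, so prefixes are right-aligned and voted column by column,
extending 5′-ward while a column has ≥ `min_support` (default 2)
contributing prefixes and its majority base reaches `min_fraction`
(default 0.8) of them. Base ties break alphabetically but a tie can never
reach the 0.8 majority, so extension stops there. Support is therefore
non-increasing toward the 5′ end, and the consensus can never exceed the
longest prefix.

**Hairpin scoring.** `max_base_pairs` is a Nussinov-style O(n³) dynamic
program maximizing nested Watson–Crick (+ G·U wobble, toggleable) pairs
with hairpin loops ≥ `min_loop` = 3 nt. It is a combinatorial stand-in
for thermodynamic folding: it ranks hairpin-forming potential and is
exactly testable against explicit structure enumeration, but assigns no
free energy and forbids pseudoknots. The default scan window is 120 nt
downstream of the SL 3′ end; `min_hairpin_pairs` = 8 marks a candidate
"canonical" together with an Sm-motif hit. The Sm-like motif default
`AATTTT` and all folding thresholds are configuration values, not
biological claims.

**SL read matching.** Suffix-anchored: the longest L ≥ `min_overlap`
(default 8) such that the L-length SL suffix matches the read's first L
bases with ≤ floor(L/10)·`max_mismatch_per_10` substitutions. Scaling the
budget with overlap keeps short overlaps strict. PolyA trimming removes a
trailing run with ≥ `min_a` = 8 A's tolerating one interior non-A; the
tolerated non-A may not sit at the run's 5′ boundary, so a single
genomic non-A base next to the tail is never swallowed.

**Peak calling.** Positions with count ≥ `min_count` (default 3) seed
peaks; same-strand seeds with gaps ≤ `merge_dist` (default 5) merge; the
span is the contiguous nonzero run around the merged seeds. Where two
peaks' runs touch, the boundary is the midpoint between their outermost
seeds (left peak keeps the middle position) — this keeps same-strand
spans disjoint, which the downstream refinement relies on. Summits are
leftmost maxima; strands never merge.

**Refinement and splitting.** All rules are strand-symmetric, stated here
for '+': an SL summit within `promote_window` (50 bp) of the locus 5′
end retargets the 5′ boundary to the summit; an SL summit ≥
`min_internal_offset` (200 bp) inside the locus splits it — the upstream
gene ends at the nearest upstream polyA summit inside the locus (else
immediately before the SL summit) and the downstream gene starts at the
summit; multiple internal summits split iteratively 5′→3′; a polyA summit
within `promote_window` of the 3′ end retargets the 3′ boundary. A gene
is flagged trans-spliced exactly when its final 5′ boundary coincides
with an SL summit. Splits that would create a gene < 50 bp are skipped
and logged. Exons are clipped sharply at new boundaries. The distance
defaults are package choices; no published values exist for them.

**Coding classification.** A simplified longest-ORF scan (3 forward
frames, first ATG per stop-free stretch, stop required, ≥ `min_aa` = 100
codons) stands in for a dedicated ORF predictor and is labelled as such.
It finds no reverse-strand or incomplete ORFs.

**Assembly utilities.** N50 is the smallest length ℓ with
Σ(lengths ≥ ℓ) ≥ total/2 and L50 the size of the minimal covering prefix
(the common convention). GC excludes N from the denominator. The
flow-cytometry estimator is the standard ratio G = size_ref ·
F_sample/F_ref; with several reference standards the per-reference
estimates and their min–max range are reported. Circularization detects
only **exact** terminal repeats (largest k ≤ len/2 with prefix = suffix);
a `--canonical-rotation` flag returns the lexicographically smallest
rotation for comparison determinism. Fractions derived from counts use
half-up rounding throughout (deterministic, independent of banker's
rounding).

## The synthetic-data generator

`sim.simulate_dataset` draws, from one seeded generator per dataset
(no global state): gene exonic lengths uniform in 300–800 bp (intronless
by default; introns configurable), strand per transcription unit,
placement order, and intergenic gaps ≥ 200 bp with the slack distributed
multinomially. It plants exactly one SL RNA cassette (SL + GT donor +
12-bp stem / 5-nt loop hairpin + `AATTTT` Sm-like motif). Counts derived
from fractions are half-up rounded: round(f·n) genes are trans-spliced
and round(p·n)//2 polycistronic pairs are formed, whose
downstream-in-transcription members are always trans-spliced (that is
what resolves a polycistron; configurations violating this are rejected).

Trans-spliced transcripts carry a 3′-terminal SL suffix with length
uniform in `sl_prefix_length_range` (10–32 by default); the first two
trans-spliced transcripts always retain the full leader, mirroring the
full-length 5′ ends routinely present in real de novo transcriptome
assemblies — without some full-length support no consensus method could
reach the complete leader. Reads (default 600 of 100 nt) are allocated
round-robin across transcripts; each trans-spliced transcript gets at
least 3 junction-spanning reads (offset 0, leader retained), the rest
sample the body uniformly. 3′-tag reads end at the transcript 3′ end with
a polyA tail of 8–20 nt. Truth alignments encode leader fragments as
leading soft-clips and polyA tails as trailing clips, with `N` operations
across introns; the initial (unrefined) model set presents each
polycistronic pair as a single run-through model.

Two deliberate constructions make noiseless recovery *exact* rather than
approximate: simulated transcripts end with two non-A bases (so polyA
trimming stops precisely at the genomic boundary), and
`simulate_mito_contig` resamples its random circle until the planted
terminal repeat is the largest on the contig (accidental longer
prefix–suffix coincidences would otherwise break inversion for very
short repeats).

**What passing tests do and do not show.** The generator produces uniform
substitution errors only — no indels, no quality degradation, no
coverage bias, no alternative isoforms, no paired ends — and the demo
consumes truth alignments in place of a real spliced aligner. Exact
truth recovery at noiseless settings validates the *logic* of each stage
and their composition; it does not measure robustness to alignment
artifacts, degraded 5′ ends, internal priming, or SL sequence variants,
all of which real data contain.

## Problem sizes

The bundled test suite runs in a few seconds: property tests use
genomes ≤ 770 kb, ≤ 500 genes and ≤ 18,000 reads; oracle equivalences use
1,000 random length multisets, exhaustive strings ≤ 5 nt plus sampled
strings ≤ 12 nt for base-pair maximization, and 150 random sequences for
the ORF scan. The acceptance script's end-to-end run uses 500 genes
(151 trans-spliced, so the recovered fraction is reported as 30.2%) —
large enough that every percentage is measured over hundreds of loci,
small enough to run in seconds on one core.

## Known limitations

* Single SL family per run; secondary abundant non-matching prefixes are
  not clustered into additional leaders.
* Substitution-only mismatch model in the genomic SL search (adequate at
  near-identity over ~32 nt; indel-containing loci would be missed).
* The peak caller has no background model, FDR control or replicate
  handling; it is a transparent threshold-and-merge formalization.
* Boundary refinement trusts summits exactly; it does not model summit
  jitter, which noisy data would introduce.
* `estimate_genome_size` consumes already-extracted fluorescence peak
  means, not raw flow-cytometry files.
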