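# Methods

## Locus model and coordinates

All coordinates are 0-based half-open internally; exports that require
1-based positions (VCF) convert at the boundary. A restriction site is the
occurrence of the enzyme's palindromic recognition motif; the **cut
position** is defined as the top-strand cleavage boundary, `motif start +
cut_offset_top` (SbfI `CCTGCAGG` cuts at offset 6, NsiI `ATGCAT` at offset
5; both leave the same 4-base `TGCA` overhang, so one adapter set serves
both). Each site yields two **RAD loci**: the upstream locus spans
`[cut − flank, cut)` and is read on the bottom strand away from the cut; the
downstream locus spans `[cut, cut + flank)` on the top strand. Intervals are
clipped at sequence ends. Soft-masked (lowercase) bases match the motif —
reference assemblies are digested including repeats — and `N` never matches.

The expected read of a locus is `residual + flank`, where the residual is
the motif remnant retained after cleavage and ligation (`TGCAGG` for SbfI,
`TGCAT` for NsiI): it is what every genuine read shows immediately after its
barcode, and it doubles as a cut-site integrity check. Under this model each
genomic flank position is covered by exactly one direction, which is why the
bidirectional filter below operates on depth balance rather than on
double-reading of the variant base.

Genome fraction is reported two ways: `genome_representation` is the naive
`2 · n_sites · flank / genome_len` shortcut for when only a site count is
known; `build_rad_loci` computes the exact interval union, which is smaller
whenever two sites fall within `2 · flank` of each other. Expected cut
spacing uses the i.i.d. base model `1 / [(g/2)^s ((1−g)/2)^(L−s)]`; a motif
impossible at the stated GC (e.g. GC bases in a GC-free genome) reports
infinite spacing explicitly rather than overflowing.

## Demultiplexing and quality filtering

Barcodes are exact-matched by default; an optional rescue accepts a single
mismatch when it identifies a unique sample (maps built by the simulator
keep pairwise Hamming distance ≥ 3, so one error cannot cross samples). The
residual must match **exactly** — a mismatch there means the read does not
start at an intact cut site, and such reads are discarded rather than
repaired. The quality filter slides a window of `ceil(0.15 · read length)`
bases in steps of one base over the barcode-trimmed read and discards the
read if the mean per-base probability-correct (`1 − 10^(−Q/10)`) in any
window falls below 0.90. The threshold is applied on the probability scale,
matching the "probability of being correct" phrasing of the procedure it
implements; a read shorter than the window is judged on a single whole-read
window. Rejection reasons are mutually exclusive and checked in order
(barcode, residual, quality), so the report's counts always sum to the
input.

## Locus assignment

Reads start at cut sites, so a general-purpose aligner is unnecessary: each
locus has one expected read sequence, indexed by its first `k = 20` bases.
A read is assigned to the unique locus within `max_mismatch = 2` Hamming
distance over the overlap; prefix collisions (duplicated flanks) are
recorded at index-build time and resolved by full-sequence comparison; reads
missing the prefix (an error in the first 20 bases) fall back to a
vectorized scan against all loci. Ties and misses are conservatively
`OFF_TARGET` so that mismapping cannot seed variant calls. Externally
aligned SAM files can be ingested instead: a primary mapped record is
on-target when its alignment boundary (start for forward strand, end for
reverse) coincides with a cut position within ±2 bp, absorbing soft-clip
jitter.

## Somatic calling and curation

Pileups count A/C/G/T per locus offset, stratified by barcode. A site is a
candidate when the tumor alternate count reaches `min_alt = 4`; candidates
failing `min_depth = 20` in either sample are flagged `low_depth`, and a
normal VAF above `max_normal_vaf = 0.02` flags `germline`. Clean candidates
are tested with the one-sided Fisher exact test (hypergeometric tail) on the
tumor/normal alt/ref table and accepted under Benjamini–Hochberg at FDR
0.05 across tested sites. The caller is intentionally plain — the substance
is the curation that RAD geometry enables:

* `single_barcode`: alternate support must span ≥ 2 distinct barcodes.
  Duplicates of one PCR-errored fragment share a barcode, so this is the
  duplicate control that positional dedup cannot provide in RAD data.
* `asymmetric_coverage`: the two directions of the call's cut site must have
  depth ratio min/max ≥ 1/3. The two flanks are disjoint sequence, so the
  filter is a depth-balance test; a collapsed or mismapped locus shows up as
  gross imbalance.

A call is `PASS` iff unflagged. The private-variant screen re-examines every
PASS call in every tissue's pileup: present means VAF ≥ 0.05, absent means
VAF ≤ 0.01 at depth ≥ 20, anything else — including an uncovered site — is
indeterminate, and a variant is private only when present in exactly one
tissue and absent in all others. The sorted-vs-unsorted comparison is a
paired two-sided t test on per-mutation VAF differences (VAFs in percent,
df = n − 1); zero variance with nonzero mean is reported as the degenerate
infinite-t limit with a warning rather than NaN.

## Copy number

Only reads assigned with zero mismatches count toward site depth (a
mismatched read cannot be trusted to measure its site), both directions
summed. Sites are tiled into non-overlapping units of 5 consecutive sites
(trailing remainders dropped; overlap was rejected so unit noise stays
independent), and the per-unit log2 ratio of test over reference is formed
after dividing each sample by its total on-target read count — so a global
library-size or ploidy-driven inflation shifts the baseline but cancels
between libraries. Units with zero reference depth are masked.

Segmentation is recursive: at each step the maximal mean-shift statistic
over all contiguous windows `[i, j)` of the segment (between-group sum of
squares of window versus complement — the circular statistic of classic
read-depth segmentation) is compared against its permutation null (1,000
shuffles of unit order within the segment, add-one-corrected p), and the
split is accepted at p ≤ 0.01. The window form is used rather than a single
split point because a segment containing two separated altered runs has no
single cut that separates the means, while a window isolates either run
directly. The recursion is deterministic given the seed. Neighboring
segments whose means differ by less than 0.3 in log2 are then merged
(smallest difference first, unit-count-weighted means; idempotent at the
fixpoint) to resolve hyper-segmentation, and segments of ≥ 3 units are
called gain/loss at |log2| ≥ 0.58 (a 1.5-fold change, halfway between
diploid and a single-copy change in a pure sample — purity dilutes observed
ratios toward zero, so impure samples need wider events or lower
thresholds).

## Phylogeny

Mutations are binary characters over samples with a third state,
indeterminate, for sites without the coverage to assert absence (depth ≥ 20
and VAF ≤ 0.01). Indeterminate entries are excluded from placement rather
than imputed: RAD locus dropout is detectable and must not masquerade as
absence. The tree is rooted at the zero-mutation normal. When all carrier
sets form a laminar family (perfect phylogeny) the tree is built directly by
containment; otherwise every rooted topology on the samples (multifurcating,
e.g. 26 topologies for 4 samples) is scored by exact two-state parsimony
(Sankoff recursion with the root fixed at 0, the trunk edge contributing one
change for a root-state-1 subtree), with deterministic lexicographic
tie-breaking. Exact search is limited to 8 samples; larger inputs are
rejected explicitly rather than silently switching to a heuristic. Each
mutation is placed by a top-down optimal labeling whose ties keep the parent
state, which lands a compatible character on the edge above the smallest
clade containing its carriers; characters still requiring more than one
change are reported as homoplasy and excluded from edge counts, so placed
plus homoplastic always equals the matrix rows. Newick output carries
per-edge mutation counts as branch lengths with deterministic child order.

## Simulator

The generator emulates the full data-generating process on one synthetic
chromosome: i.i.d. sequence at a chosen GC with exactly `n_sites` motifs
planted one per equal slot (guaranteeing ≥ `2 · flank + motif` spacing;
accidental motif occurrences are resampled away, so digestion recovers
exactly the planted sites); a clone tree whose edges carry chosen numbers of
heterozygous SNVs placed inside locus flanks but never inside motifs; CNV
events as spans with a copy ratio; and barcoded reads `barcode + residual +
flank` with per-locus fragment counts Poisson(depth × local copy ratio).
A fragment carries each sample mutation with probability `0.5 × purity`
(expected VAF of a heterozygous, diploid variant at that purity), may gain a
pre-duplication PCR substitution (0.001/base) shared by all its duplicate
reads, picks one of the sample's four 5-bp barcodes, and is emitted as
`1 + Poisson(d/(1−d))` reads so the expected duplicate fraction is `d`
(default 0.15). Sequencing errors are uniform substitutions at the phred-
implied rate (default Q30), applied per read over the whole read including
the barcode; `seq_error_rate` can override the rate (e.g. 0) while quality
strings stay phred-consistent. All randomness flows from the single
mandatory seed; identical configurations are byte-identical, including
FASTA/FASTQ/manifest exports.

Defaults mirror the study design the package targets: SbfI, 100 bp flanks,
four barcodes per sample, ~350× per-locus depth, tumor purity 0.6 (expected
VAF 0.3). What the simulator does **not** model: indels and structural
variants other than copy-ratio spans, non-uniform or position-dependent
error profiles, GC-dependent amplification bias, barcode indels, allele
dropout from mutations inside recognition motifs (mutation placement
excludes motifs by default), and multi-chromosome genomes. Passing tests
therefore demonstrate correctness of the pipeline's logic under the stated
generative model, not robustness to every artifact of real libraries.

## Problem sizes and test conditions

The replicated properties run at the study's stated conditions scaled to
desk size: somatic sensitivity/specificity uses 50 sites (100 loci) at 350×,
purity 0.6, Q30, 20 replicates, with PCR substitution and duplication
disabled — with them enabled, coincident duplicated PCR errors at one
position can legitimately clear every filter, which is precisely the failure
mode the dedicated artifact stress test exercises (30 forced single-barcode
duplicate reads at an unplanted site, suppressed by the barcode filter in
every replicate). CNV recovery plants a 2× gain over 10 of 50 units at
40 reads/site in a pure tumor; end-to-end phylogeny uses the 160/4/8
two-tumor design at 100×, purity 0.8, with duplicates on. The acceptance
script re-runs the same computations at 5 replicates each.

## Known limitations

* The exact-test caller is a stand-in: it has no base-quality model, no
  local realignment, and no contamination estimate, so its absolute
  sensitivity on real data would trail a production somatic caller.
* Depth-ratio CNV calling reports relative copy state only; purity/ploidy
  deconvolution and allele-specific copy number are out of scope.
* The assignment matcher requires reads to begin at cut sites; it is not a
  general aligner and does not handle indels in the flank (such reads go
  off-target and are lost to depth, not miscalled).
* Exact tree search is exponential in sample count; beyond 8 samples the
  package refuses rather than approximates.
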