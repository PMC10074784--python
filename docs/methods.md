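# Methods

## Detection model

`fusionclip` calls a gene fusion from two alignment signatures left by
junction-spanning cfDNA fragments: discordant mate pairs (one read per gene
window) and soft-clipped junction reads (aligned in the 5' gene with the 3'
gene's sequence retained as a terminal `S` CIGAR segment). Only the 5'
(EML4) window is scanned; the reciprocal scan (ALK-anchored reads clipped
into EML4) is deliberately not performed, matching the published procedure
the detector reimplements. Strand annotations on the windows are
informational only — the procedure never branches on them.

A sample is positive iff

    n_pairs ≥ min_pairs   and   n_clip_reads ≥ min_clip_reads

where `n_pairs` counts **distinct read names** (a fragment is one pair no
matter how many of its records fall in the window — mate-overlapping
evidence must not double-count) and `n_clip_reads` counts soft-clipped
evidence records among the mate-filtered candidates. Negative samples
carry their counts but an empty evidence set.

### Breakpoint definition and tie-breaks

The breakpoint of one evidence read is the reference coordinate of the
aligned base adjacent to the used soft clip: for a right-end clip
`pos + (reference-consumed length) − 1`, for a left-end clip `pos`. When
both read ends are clipped the longer clip is used (junction clips dominate
adapter/quality clips in length); equal lengths use the right end. Evidence
whose implied breakpoint falls outside the 5' window (reads overlapping the
window edge) is discarded so every reported breakpoint is in-window.

The consensus breakpoint is the mode of the per-read breakpoints; ties
break toward the smallest coordinate. All tie-breaks are deterministic, so
identical input yields a bitwise-identical report.

### Flanking sequences

The 5'-side flank is a per-column majority vote over the aligned bases of
the consensus-supporting reads at reference positions
`[consensus − flank_len + 1, consensus]`; columns with no coverage or a
tied vote emit `N` (never IUPAC codes — the output feeds primer design).
The 3'-side flank votes over the clipped bases ordered junction-outward
(index 0 adjacent to the junction); its length is
`min(flank_len, longest clip)`, and columns beyond a shorter clip simply
lose that read's vote. Clipped bases are reported exactly as stored in the
record, i.e. *not* re-complemented onto the 3' gene's annotated strand:
for EML4/ALK the genes lie on opposite strands, so the 3' flank reads along
the fused allele, which is what a junction-spanning dPCR assay needs.
`flank_len` defaults to 20 bp per side.

### Breakpoint depth

The ctDNA-burden surrogate is the number of filter-passing records whose
aligned span covers the consensus position via `M`, `D`, `=` or `X`
(a deletion bridging the position still covers it; an `N` skip does not).

### Filtering defaults

Unmapped, mate-unmapped, secondary, supplementary, QC-fail and
duplicate-flagged records are excluded — inputs are modeled as
position-deduplicated BAMs, and split/duplicate artifacts must not inflate
the evidence counts. No mapping-quality threshold is applied by default
(none is published); `FlagPolicy(min_mapq=...)` exposes one. Chromosome
naming dialects (`chr2` vs `2`) are reconciled against the BAM header
before failing. Overlap with a window is computed on the
reference-consuming span (`M,D,N,=,X`), boundaries inclusive, 1-based at
every interface.

### Target windows

The hg38 windows shipped for EML4-ALK are the published detection windows.
hg19 is not published; the shipped values are liftover-derived UCSC gene
spans, marked as derived in `src/fusionclip/data/targets.json`, and any
window set can be supplied via a JSON config (`load_target_config`), which
is also the extension point for other fusion partners.

## Simulator

The generator emulates the assay the detector targets: cfDNA fragments
with length ~ Normal(165, 10) truncated to `[read_len/2, 2·mean]`,
sequenced as 100 bp paired-end reads with constant base quality. A
fusion-positive sample mixes junction-region fragments drawn from a fused
template — the 5' window sequence up to its breakpoint followed by the
reverse complement of the 3' window sequence down from its breakpoint
(modeling the EML4/ALK opposite-strand inversion) — with wild-type
fragments placed uniformly over both windows at a configurable mean depth.
Fragment midpoints for fusion fragments are uniform within one mean
fragment length of the junction, so the junction-spanning fraction has a
closed form by enumeration (the test suite checks the observed fraction
against it).

The simulator is its own aligner: a read wholly inside one gene segment is
emitted fully aligned (minus-strand geometry handled by segment
orientation); a junction-spanning read anchors on the side with at least
`min_anchor` (default 20) template bases — the longer side when both or
neither qualify, ties to the 5' gene — and carries the other side as a
soft clip adjacent to the junction. This removes any third-party aligner
from the test loop at the cost of idealized behavior. Same-gene pairs are
flagged proper; cross-gene pairs are left anomalous, as a real aligner
would. Every sample ships a truth record (breakpoints, junction read ids,
cross-gene pair ids, window sequences) and all randomness flows from one
seeded generator, so a configuration reproduces byte-identical truth.

What the simulator does **not** model: indels and PCR artifacts, duplicate
reads and UMIs (inputs are modeled as already deduplicated), capture
efficiency and GC bias, quality-score variation, and real soft-clip length
distributions from production aligners. Passing tests therefore
demonstrate the algorithm's correctness on idealized evidence, not its
sensitivity on degraded real-world libraries.

## Statistics

Detector-vs-detector cohort comparisons use the two-sided Fisher exact
test under the probability-mass rule — the p-value sums all
margin-preserving tables whose probability does not exceed the observed
table's (relative gate 1e-7) — computed via `scipy.stats.fisher_exact`,
which implements exactly this rule; the test suite verifies it against an
integer-exact enumeration oracle for every table with total ≤ 40.
Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are reported as absent
(never 0) when undefined.

## Problem sizes and numerical choices

Tests and the acceptance script simulate on 4 kb stand-in windows rather
than the 163/729 kb gene windows: the algorithm is window-size-agnostic
and small windows keep 100-sample cohorts cheap. Positive cohort samples
use 60 junction-region fragments over 30× background — a clearly positive
sample in which ≥ 2 detectable junction reads arise with overwhelming
probability; fusion-free samples sweep 10–500× coverage. Fragment-length
sd defaults to 10 bp (only "approximately 165 bp" is published for cfDNA).
The junction-fraction check uses sd = 0 so the enumeration oracle is
exact; stochastic checks use 3-standard-error bands at fixed seeds.

## Known limitations

* Only the 5'→3' orientation printed above is scanned; reciprocal or
  multi-breakpoint (clonally heterogeneous) events are out of scope.
* Fusion allele fraction and EML4-ALK variant (v1/v3) annotation are not
  estimated.
* The exact consensus/tie-break rules and default flank length of the
  original implementation are unpublished; the deterministic choices here
  are documented substitutes.
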