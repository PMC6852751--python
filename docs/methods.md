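# Methods

This note documents the models, parameter choices and numerical conventions
behind `tdnascout`, and what the synthetic benchmark does and does not show.

## Coordinates and event model

All in-memory and JSON coordinates are 1-based inclusive; BED output is the
only 0-based half-open surface. An integration event is "a contiguous vector
fragment replaces a host interval": `del_start > del_end` (by one) encodes a
zero-length deletion, i.e. a clean insertion. Orientation `-` means the
reverse complement of the vector fragment is inserted. This model covers
both observed event classes (small fragment/small deletion inside a gene;
large cassette/large deletion) and clean insertions. It deliberately
excludes junction microhomology and filler sequence, tandem multi-copy
arrays, and heterozygosity (transformant lines are clonal), so one haplotype
per genome is simulated and called.

## Synthetic data

`simgen` draws i.i.d. bases at a target GC (default 36%, a typical broadleaf
tree genome), a vector of pGWB2-like geometry (12.5 kb, cassette at
3,967–12,125 with a 1,089 bp transgene CDS), and reads from the mutant
haplotype:

- short reads: 100 bp pairs, insert 400 ± 40 bp (FR), depth 29×, per-base
  substitution rate 0.5%, constant Q30;
- long reads: lognormal lengths (σ=0.25, mean ≈ 8,055 bp, truncated to
  [500 bp, contig]), depth 30×, substitution/insertion/deletion rates
  2.7/2.7/2.6% (≈8% total), constant Q12.

Depth, read length, insert size, long-read length and the error-rate split
are the study conditions the generator emulates; qualities are constant
because the pipeline uses them only in QC. Read ids encode the true origin
(contig, start, strand), which is what makes exact oracle tests possible.

The default fixture plants the two mirrored events on 200 kb and 120 kb
contigs. Event placement is nudged by the smallest offset (same lengths,
same vector interval) such that no junction carries chance single-base
homology between flank and insert: without this, the exact breakpoint is
mathematically unidentifiable from any read (two placements describe the
same mutant sequence), and the zero-error "exact recovery" check would test
an arbitrary labeling convention rather than the algorithm. Real data does
carry junction microhomology; on such junctions any caller, including this
one, is accurate only up to the homology length.

What passing tests on this generator do *not* show: robustness to
instrument-specific error profiles (homopolymer bias, quality-correlated
errors), to repetitive host genomes beyond the planted vector duplication,
to tandem T-DNA arrays, or to contamination. The i.i.d. host sequence is
nearly repeat-free, so mapping is easier than in a real plant genome; the
mapq filter and occurrence-capped index are exercised only lightly.

## Mapper

`litemap` is a deterministic seed–cluster–extend mapper: exact k-mer seeding
(k=15 short / 13 long, occurrence cap 50), diagonal clustering of anchors
per (contig, strand), then whole-read infix alignment (edlib) against the
implied window, accepted when the edit distance is within `band` (0.15 of
read length short, 0.25 long). A read crossing an insertion junction fails
that acceptance and is emitted as one primary alignment over the chained
span with terminal soft clips — no supplementary alignments; the junction
screen re-maps the clip itself. Mapping quality is `min(60, 6·(best −
second-best cluster score))`, 0 on ties, with ties broken toward the
lexicographically smallest contig and leftmost position. The mapper exists
so the pipeline has no external binary dependency; the screening stage
consumes plain SAM, so BWA/minimap2 output can be substituted.

`align_banded` returns the exact unit-cost edit distance: the band is a
performance cap and the computation falls back to unbounded alignment when
the optimum exceeds it. Tests compare it against an independent full-DP
implementation.

## Screening, clustering, confirmation

Defaults (all overridable in `PipelineConfig`): min mapping quality 20, min
clip 15 bp, clustering window = insert mean + 4 SD (560 bp), min evidence 3
(pairs + vector-mapping splits), long-read extraction flank 2 kb, min 1
supporting long read for confirmation, containment k=21 with ≥5 distinct
shared k-mers, correction k=13 with min coverage 3. The evidence thresholds
are not taken from any published value — the source procedure reports
screening without thresholds — so they are explicit, conservative defaults.

Hybrid correction is a pileup consensus, not an iterative remapper: short
reads are anchored to each target long read via shared 13-mers, aligned with
edit distance, and each long-read column takes the majority over covering
short-read bases, with deletion votes and majority insertions applied and
uncovered columns left untouched. Two numerical details matter. First,
indel placement inside repeats is ambiguous and alignment-dependent, so
every indel run is left-normalized before voting; otherwise votes split
across equivalent columns and homopolymer-adjacent errors survive. Second,
alignments flush against the alignment window edge (short reads overhanging
the long-read end) are discarded — their overhang is crammed in as spurious
edits that poison low-coverage edge columns. On error-free input the
consensus is a fixed point; at the default error rates it removes ≳99% of
long-read errors on covered columns.

## Breakpoint resolution

Each vector-containing read is oriented to the genome-forward strand (by
genome anchor count), decomposed into diagonal anchor runs against the site
window ± 5 kb of the genome and against both vector strands (runs split on
offset jumps > 15 bp or anchor-free query gaps > 200 bp, ≥ 3 anchors each),
and each junction it spans is refined by exact match extension from the
nearest anchor. A left junction yields `del_start` and one vector bound
(`v_start` for `+`, `v_end` for `-`); a right junction yields `del_end` and
the other bound. Reads decomposing into ≥ 4 runs are logged and excluded as
complex. Per-quantity aggregation is the lower median (ties toward the
smaller coordinate, deterministic); the reported `breakpoint_ci` is the
maximum absolute deviation of per-read estimates from that median.
Orientation is the majority vector-strand vote.

Sites only supported by pairs/splits stay `candidate` with the window as
interval and no vector interval. A deletion larger than the clustering
window necessarily appears as two one-sided sites; adjacent confirmed
one-sided calls on one contig with consistent orientation and a well-formed
combined vector interval are merged into a single event. The anchor-run
split rule implies a resolution floor: inserted fragments shorter than
~220 bp leave the two genome flanks indistinguishable from one run and are
not resolved to base precision (the default events are 388 bp and 8,159 bp).

## Annotation, PCR, phenotype formulas

Deletion impact is a per-base decomposition over gene models with precedence
CDS > five_prime_UTR > exon > intron (gene span minus exons) > intergenic,
so the per-class counts always sum to the deletion length; intron features
are inferred because GFF3 rarely encodes them. In-silico PCR is
sequence-identity matching (≤ 1 mismatch, exact 3'-terminal 3 bases, max
product 5 kb) with products measured 5'-to-5'; thermodynamics are out of
scope because junction verification is by product presence and length.

The growth model is H(t) = a + (b−a)/(1+exp(−k(t−t0))), fitted by
Levenberg–Marquardt least squares with data-driven initialization (a=min,
b=max, t0 at the median height, k from the steepest finite-difference slope
× 4/(b−a)). The rapid stage is bounded by the third-derivative zeros
t0 ± ln(2+√3)/k — the standard convention; published tables that use a
different (unstated) boundary rule will differ slightly in t1/t2/GR while
agreeing in the internally consistent ratios. Closed forms used and tested
symbolically: stage duration 2·ln(2+√3)/k, stage growth (b−a)/√3, peak rate
k(b−a)/4. The annual growth used as the RRA denominator is a user-supplied
measured total, not derived from the asymptotes. Stage quantities are
reported at two decimals. Wood composition and 2^−ΔΔCT are exact algebraic
identities and tested as such. ORF search takes the longest ATG-initiated
stop-terminated frame on either strand under the standard genetic code
(min 90 nt, configurable), so a full-length 1,770 nt ORF translates to 589
aa.

## Problem sizes

The default benchmark is two contigs totalling 320 kb at 29×/30× — about
three orders of magnitude below a tree genome, chosen so the full chain
(simulation, mapping, correction, resolution) runs in about a minute per
configuration while every stage still sees the evidence structure it was
built for (both junction classes, both orientations, a deletion far larger
than the insert-size window, and an internal vector duplication that forces
mapq-0 handling). Unit tests use a 100 kb variant of the same scenario.

## Known limitations

- Single contiguous fragment per site: tandem/inverted multi-copy arrays are
  flagged as complex reads and excluded, not resolved.
- Junction microhomology is called up to an arbitrary placement within the
  homologous stretch (inherent ambiguity).
- Inserted fragments < ~220 bp are detected but not base-resolved.
- The mapper targets simulated error profiles; for real data, substitute
  BWA/minimap2 SAM via `--sam/--long-sam`.
- Endogenous sequences homologous to the vector are suppressed by the
  mapq ≥ 20 screen rather than reported as low-confidence candidates.
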