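# Methods

cgmap aligns long reads and contigs to a reference with the classic
seed–cluster–chain–refine architecture, built around an *exact* solution
of fragment chaining under a concave gap cost.  This note records the
model, the algorithmic choices, the parameters that matter, and what the
synthetic data used by the tests does and does not demonstrate.

## Chaining model

A fragment αᵢ is a weighted box on the query × target plane: a
lower-left start point (xsᵢ, ysᵢ), an upper-right end point (xeᵢ, yeᵢ),
and a weight lᵢ.  A chain C is an ordered subset in which each
fragment's start is strictly above and to the right of its
predecessor's end, scored as

    score(C) = Σ l_{Cj} − Σ gap(|f_end(Cj) − f_start(Cj+1)|),

where f = y − x is the forward diagonal and `gap` is concave and
non-negative.  The default gap cost is a·ln(d + 1) + b with a = 0.25,
b = 1; concavity (non-increasing increments) is validated at
construction and a convex cost raises an error.  A concave cost charges
large jumps — structural variants — only logarithmically more than
small ones, which is what keeps an SV inside a single alignment instead
of splitting it.

Scores subtract the gap term.  The natural logarithm is used, and the
worked six-fragment example in `cgmap.chain` evaluates to 2.8267,
printed as 2.8 at one decimal.

## Exact chaining in O(n log² n)

The quadratic predecessor scan is replaced by divide-and-conquer
subproblems.  The occupied columns (distinct x of all points) are halved
recursively; each non-leaf node is a *column subproblem* whose A-part
holds the end points of the left half and whose B-part holds the start
points of the right half; leaves (one column) have an empty A-part.
Rows are decomposed the same way.  Each start point therefore sees the
entire half-plane to its left as a disjoint union of O(log n) A-parts,
and the half-plane below it likewise (tested directly as the coverage
invariant).

Legality is encoded on diagonals.  In a column subproblem x-order is
guaranteed by construction, and a predecessor is valid iff its diagonal
satisfies f_end ≤ f_start, which forces the y-order; in a row subproblem
y-order is guaranteed and f_end > f_start forces the x-order.  Both
families, and the two reverse-diagonal families of the inversion
extension, are instances of one generic engine: diagonals are
transformed (negated where necessary) so the condition always reads
"key(end) ≤ key(start)" with keys increasing along D_I/E_I and the gap
argument equal to the key difference.

Each subproblem keeps the arrays D_I/D_V/D_P (per-diagonal best
predecessor scores) and E_I/E_V/E_P for the start-point diagonals, a
progress index E_L, and a block structure E_B.  E_B maintains, per start
diagonal, the best `value − gap(distance)` over candidates supplied in
increasing diagonal order.  Concavity makes the region where a new
candidate beats the incumbent structure a contiguous prefix of its
validity range, so an update is a walk over whole blocks plus one binary
search — O(log |E_I|) amortised — and a query is a binary search.

Points are processed synchronously in Cartesian (x, then y) order, start
points before end points at coordinate ties (a start may not chain to a
coincident end).  A start consumes the prefix of D_V its diagonal
permits (advancing E_L), queries E_B in each subproblem of its SB list,
and takes the maximum, clamped at 0 (a chain may start fresh).  An end
publishes its fragment's score into the D_V entry of each subproblem in
its SA list.  A short argument shows that in every family, any end point
on a diagonal needed by a start precedes that start in Cartesian order,
so each D_V entry is final when first consumed and each candidate is
updated exactly once, in order — no asynchronous blocking is needed.
This property is not assumed: an assertion fires if a consumed diagonal
was unsolved, and the chainer is tested for exact score equality against
a quadratic reference on thousands of random instances.

Counting Update/query calls plus their internal binary-search steps
across n = 2⁷…2¹³ gives a ratio to n·log₂²n that drifts by less than 3%
across the range.

## Inversions

Each fragment also carries an upper-left start s2 = (xs, ye) and a
lower-right end e2 = (xe, ys).  A reverse link chains s2(αᵢ) to e2(αⱼ)
when xe_j < xs_i and ys_j > ye_i, penalised by a concave function of the
reverse-diagonal (x + y) difference, plus an optional constant
orientation-switch penalty (default 0, i.e. the model exactly as the
recurrence states it).  Column-2/row-2 subproblem families mirror the
forward ones with reverse diagonals; a fragment's value is
max(Score(s1), Score(s2)) + l and is published through both end points.
A block of anti-diagonal fragments (a sequence inversion) is traversed
by reverse links while the flanks attach through the ordinary forward
geometry of the block's bounding boxes, so an inverted segment stays in
one chain.  Zero-width fragments sweep e2 before s2; the engine solves
such a start lazily at the end point, which is safe because everything
it depends on lies at strictly smaller x.

## Indexing

The global index samples canonical (k, w) minimizers (leftmost least
k-mer per window; N-bearing k-mers never qualify) and then applies three
density controls: k-mers of genome-wide multiplicity > F_M are removed;
the target is partitioned into W_G-length intervals; per interval,
survivors are retained in increasing multiplicity (ties by position)
until N_M are kept.  Library defaults are k=15, w=10, F_M=50, N_M=10,
W_G=1000, with the finer local index at k=7, w=5, W_l=1000 — deliberately
sparse, desk-scale values.

The technology presets index with W_G=250, N_M=15 instead.  On an
i.i.d. toy genome every k-mer has multiplicity 1, so the thinning rule
degenerates to "keep the first N_M positions of each interval"; a
smaller interval with a proportional budget spreads retained seeds
evenly enough that any kilobase read overlaps seeds.  On a real genome
multiplicities differ and the rule behaves adaptively as intended.

Anchors record the query/target offsets of a shared canonical k-mer;
strand is recovered by comparing the two orientation bits, so reverse
matches need no sequence storage.  The local index is one independent
minimizer table per W_l tile, positions absolute.

## Clustering

Rough clustering sorts anchors by (diagonal, x) — forward diagonal for
forward anchors, reverse diagonal for reverse — and cuts at diagonal
gaps > D_R (200 for CLR/ONT, 150 for HiFi/contigs); intervals below
minClusterSize (3 / 10) are noise and dropped.  Low-accuracy presets
chain all retained anchors directly; high-accuracy presets refine each
rough cluster into fine clusters first: runs of anchors whose k-mer is
unique within the cluster seed the fine clusters, runs are merged when
facing corners differ by < D_F = 500 in diagonal and ≤ G_dist in the
plane, non-unique (tandem-repeat) anchors inside the trapezoid between
merged runs are absorbed, and the rest are discarded.  G_dist has no
published value; the default is 5000 bases, large enough that desk-scale
run gaps never split a colinear alignment, and configurable.  The
trapezoid test is applied between consecutive merged runs only.
Overlapping fine clusters are split at each other's boundary
coordinates (both axes); split corners are recomputed from the member
anchors, which are never duplicated.  Split clusters become
super-fragments (corners as start/end, weight = summed anchor length)
for chaining.

## Refinement and alignment

The chained anchors of the best locus are refined per maximal
same-strand segment.  A reverse segment is normalised by
reverse-complementing its query interval, so refinement is forward-only.
The outermost segments are extended to the read ends and interior
boundaries to the midpoint of the gap between segments, so breakpoints
are covered.  Local (k_l, w_l) anchors are generated by cross-matching
the tile pairs the coarse chain touches, same-diagonal Cartesian-adjacent
anchors are merged into fragments weighted by their span, and a second
forward chaining pass selects the final anchor set.

Between consecutive chained fragments the sequence is aligned by a
two-band dynamic program: a lower band follows the main diagonal, an
upper band follows the end diagonal (offset l_t − l_q), and one
penalty-free horizontal jump may cross from lower to upper — the single
free gap that models an SV between anchors.  Scoring is +2 match, −4
mismatch, δ = 3 per ordinary gap base, band B = 10 (all configurable;
only relative magnitudes matter).  When the no-gap banded path reaches
the corner with a better score it is preferred, so small gaps are still
penalised normally.  The implementation is tested for exact score
equality against an unbanded three-state reference DP whenever the band
is unconstrained, and for preserving indels longer than the band as a
single CIGAR gap under the production band.  Terminal soft-clips are
converted into aligned bases when a global alignment of the clipped
piece against the adjacent target scores positively; inter-anchor
regions beyond 50 kb are reported as unaligned junctions rather than
aligned base-level.  Gap placement among co-optimal traceback choices is
deterministic (fixed operation preference); exact breakpoint placement
within a homology tract is therefore conventional, as it is for any
aligner.

## Pipeline policies

Candidate loci are rough-cluster groups separated by more than a read
length on the target; each is chained independently and the best score
wins.  MAPQ is an invented, deliberately simple monotone margin rule:
60 for a unique locus, 0 for an exact tie, otherwise
round(40·margin/best) clamped to [0, 60].  The primary record is the
longest segment on the read's majority orientation; other segments are
supplementary (reverse-strand ones carry the inversion signal).  SAM
(with @HD/@SQ/@PG) and PAF writers emit byte-identical output for fixed
inputs; records are validated by a pysam round-trip in the tests.

The mapping-evaluation utility classifies a primary record as correct
when its target interval overlaps the read's truth interval by at least
a given fraction (10/40/70%) of the truth length, reported per MAPQ
cutoff.

## Synthetic data

The simulator generates i.i.d. genomes (optionally salted with a tandem
array), applies non-overlapping SVs — INS, DEL, INV, INVDEL (inversion
flanked by symmetric deletions) and INVDUP (adjacent inverted copy) — in
one left-to-right pass that records exact truth coordinates on both the
source genome and the haplotype, and samples uniform reads with a
per-base multinomial error model (mismatch/insertion/deletion, random
strand).  Error presets: HiFi ≈ 1%, ONT ≈ 12%, CLR ≈ 20% total error.
Everything is deterministic per seed.

The end-to-end test conditions are a 50 kb genome carrying one 100-base
INS, one 100-base DEL, one 600-base INV and one 600-base INVDUP, read at
20× with 10%-error 1–2 kb reads; "spanning" means the truth interval
covers the event with ≥ 150 bases of flank on both sides.  Oracle
comparisons use up to 1000 forward and 500 inversion random instances
(n ≤ 100 / n ≤ 60), 200 alignment pairs of length ≤ 300, and operation
counts at n up to 2¹³ — sizes chosen so the whole suite runs in a few
minutes on one core.

What the simulation does *not* capture: real error profiles are
context-dependent (homopolymer indels dominate ONT error, not i.i.d.
multinomials); real genomes contain segmental duplications and
satellite arrays far more repetitive than a salted tandem array; and
real SV are clustered and nested.  Passing tests therefore demonstrate
the correctness of the algorithms and the qualitative SV-preservation
behaviour, not genome-scale mapping accuracy or SV-calling F1.

## Numerical conventions

Coordinates are 0-based, half-open everywhere internally; SAM output
converts to 1-based at the boundary.  Chain scores are floats; ties are
detected at a relative tolerance of 1e-9 and broken toward the smaller
fragment index, making reported chains deterministic.  Co-optimal chain
counting is a separate exhaustive traceback over the chainability DAG
and is intended for small instances only.

## Known limitations

Translocations are not chained.  The block structure's Python lists give
the stated O(log n) comparison counts but array edits are linear-time
memory moves; this is irrelevant at desk scale.  MAPQ is not calibrated
to an error probability.  Alignment is not base-quality aware, and the
single-free-gap model handles one SV per inter-anchor interval — two
distinct SVs between adjacent anchors would share one gap.
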