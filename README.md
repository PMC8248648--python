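# cgmap

A desk-scale long-read aligner built around **exact sparse dynamic
programming chaining with a concave gap cost** (CG-SDP), for people who
study alignment-driven structural-variant (SV) discovery: method
developers who need a transparent, fully tested reference for
concave-gap chaining, inversion-aware chaining, and single-free-gap
banded alignment, and teachers who want a working seed–cluster–chain–
refine aligner small enough to read.

## The model

Given fragments αᵢ = ((xsᵢ, ysᵢ), (xeᵢ, yeᵢ), lᵢ) on the query × target
plane, chaining selects C ⊂ {1..n}, each fragment strictly above-right
of its predecessor, maximising

    Σⱼ l_Cⱼ  −  Σⱼ gap(|f_end(Cⱼ) − f_start(Cⱼ₊₁)|),

with f = y − x the forward diagonal and `gap` concave (default
0.25·ln(d+1) + 1).  A concave cost penalises a 1 kb jump only
logarithmically more than a 10 bp one, which is what keeps structural
variants inside a single alignment.  The optimum is found exactly in
O(n log² n): columns and rows are halved into divide-and-conquer
subproblems, each holding per-diagonal arrays (D_I/D_V/D_P,
E_I/E_V/E_P) and an online block structure that exploits concavity to
answer best-predecessor queries in O(log n); points are processed
synchronously in Cartesian order.  Adding an upper-left start and
lower-right end point per fragment, with a concave cost on
reverse-diagonal (x + y) differences, extends the same machinery to
chains that traverse inversions.

Around that core: an adaptive minimizer index (k, w plus the density
controls F_M, N_M, W_G), rough/fine anchor clustering with boundary
splitting, local-minimizer refinement, and a two-band alignment with a
single penalty-free gap between anchors.  A seeded simulator generates
the toy genomes, SV haplotypes (INS/DEL/INV/INVDEL/INVDUP) and
error-bearing reads used throughout the tests.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

The chainer on its six-fragment demonstration instance (match bonus 2,
gap 0.25·ln(d+1)+1):

```sh
$ cat frags.txt        # xs ys xe ye weight
0 0 2 2 2
3 4 6 7 2
4 1 7 4 2
5 4 8 7 2
7 1 10 4 2
11 6 13 8 2
$ cgmap chain --fragments frags.txt
score   2.826713
chain   0+ 1+
```

Two fragments are chained (weights 2 + 2) across a forward-diagonal
jump of 1, costing 0.25·ln 2 + 1 ≈ 1.173: the optimal value is 2.827,
i.e. **2.8** at one decimal.  Three distinct chains tie at this value
(`cgmap.chain.enumerate_optimal_chains` lists them); the reported one is
the deterministic smallest-index choice.

An end-to-end toy run — simulate a 20 kb genome with 27 ONT-like reads,
align, and evaluate:

```sh
$ cgmap simulate --length 20000 --depth 2 --preset-error ont --seed 5 --out-prefix demo
wrote 27 reads over a 20000 bp genome with 0 SV(s)
$ cgmap align -r demo.ref.fa -q demo.reads.fq --preset ONT -o demo.sam
```

`demo.sam` holds one primary record per read (`@HD`/`@SQ`/`@PG` header,
FLAG/POS/MAPQ/CIGAR/SEQ).  Evaluating the placements against the
simulator's truth intervals at the 10/40/70% overlap fractions:

```python
>>> from cgmap import align, evaluate_mapping
>>> recs = list(align("demo.ref.fa", "demo.reads.fq", "ONT"))
>>> evaluate_mapping(truth, recs)          # truth from demo.truth.tsv
{0.1: {0: 1.0, 20: 1.0}, 0.4: {0: 1.0, 20: 1.0}, 0.7: {0: 1.0, 20: 1.0}}
```

All 27 reads are placed on their true interval at every overlap
stringency and MAPQ cutoff.

The `simulate` subcommand also injects SVs (`--svs` with `type pos
length [flank]` rows); reads crossing a 100-base insertion or deletion
carry a single CIGAR gap of the right type and size, and reads crossing
an inversion produce a reverse-strand supplementary record over the
inverted interval — the behaviour the concave-gap chain exists to
deliver.

## Layout

| module | contents |
| --- | --- |
| `cgmap.chain` | fragments, concave gap costs, block structure, subproblems, CG-SDP chainer + quadratic/enumeration oracles |
| `cgmap.invchain` | inversion-aware chaining + its oracle |
| `cgmap.index` | minimizers, adaptive global index, tiled local index, anchors |
| `cgmap.cluster` | rough/fine clustering, boundary splitting |
| `cgmap.refine` | local anchors, diagonal merging, banded one-free-gap alignment, CIGAR stitching |
| `cgmap.pipeline` | presets, end-to-end aligner, MAPQ, mapping evaluation, SAM/PAF |
| `cgmap.simdata` | seeded genomes, SV haplotypes, read simulation, truth tables |

Not goals: genome-scale performance, BAM/CRAM output, translocation
chaining, SIMD.
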