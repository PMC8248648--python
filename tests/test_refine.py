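"""Local anchoring, diagonal merging, one-free-gap banded alignment,
and chain stitching."""

from __future__ import annotations

import numpy as np
import pytest

from cgmap.chain import Fragment, GapFunction, chain_fragments
from cgmap.index import Anchor, LocalIndexParams, build_local_index
from cgmap.refine import (
    BandedAlignParams,
    banded_one_gap_align,
    cigar_spans,
    local_anchors,
    merge_diagonal_anchors,
    stitch_alignment,
)

from conftest import random_seq

LOCAL = LocalIndexParams(7, 5, 500)


# ---------------------------------------------------------------------------
# local_anchors
# ---------------------------------------------------------------------------


def _chain_anchor(x, y, k=15):
    return Anchor(x=x, y=y, k=k, strand="+", kmer=0)


def test_identical_substrings_give_dense_single_diagonal(rng):
    s = random_seq(rng, 400)
    qi = build_local_index(s, LOCAL)
    ti = build_local_index(s, LOCAL)
    anchors = local_anchors(s, s, [_chain_anchor(10, 10), _chain_anchor(380, 380)], qi, ti)
    on_diag = [a for a in anchors if a.f == 0]
    assert len(on_diag) >= len(s) / 10  # dense at k_l resolution
    for a in on_diag:
        assert s[a.x : a.x + a.k] == s[a.y : a.y + a.k]


def test_snp_leaves_an_anchor_gap_around_it(rng):
    q = random_seq(rng, 300)
    pos = 150
    t = q[:pos] + ("A" if q[pos] != "A" else "C") + q[pos + 1 :]
    qi = build_local_index(q, LOCAL)
    ti = build_local_index(t, LOCAL)
    anchors = [a for a in local_anchors(q, t, [_chain_anchor(5, 5), _chain_anchor(280, 280)], qi, ti) if a.f == 0]
    # brute-force k_l-mer matching oracle around the SNP
    k = LOCAL.k
    for a in anchors:
        assert q[a.x : a.x + k] == t[a.x : a.x + k]
        assert not (a.x <= pos < a.x + k)  # no anchor covers the SNP


def test_tiles_without_chained_anchors_are_not_compared(rng):
    q = random_seq(rng, 1000)
    t = q  # identical, but the chain only touches the first tile
    qi = build_local_index(q, LOCAL)
    ti = build_local_index(t, LOCAL)
    anchors = local_anchors(q, t, [_chain_anchor(10, 10), _chain_anchor(100, 100)], qi, ti)
    assert anchors
    assert max(a.x for a in anchors) < 500 + LOCAL.w_local  # far tiles untouched


# ---------------------------------------------------------------------------
# merge_diagonal_anchors
# ---------------------------------------------------------------------------


def test_adjacent_same_diagonal_anchors_merge_with_span_weight():
    a = [Anchor(0, 0, 7, kmer=1), Anchor(5, 5, 7, kmer=2)]
    frags = merge_diagonal_anchors(a)
    assert len(frags) == 1
    fr = frags[0]
    assert (fr.xs, fr.ys, fr.xe, fr.ye) == (0, 0, 12, 12)
    assert fr.weight == 12.0  # last end point minus first start point


def test_interleaving_anchor_on_other_diagonal_blocks_merging():
    a = [Anchor(0, 0, 7, kmer=1), Anchor(2, 30, 7, kmer=3), Anchor(5, 5, 7, kmer=2)]
    frags = merge_diagonal_anchors(a)
    assert len(frags) == 3


def test_distinct_diagonals_stay_separate():
    a = [Anchor(0, 0, 7, kmer=1), Anchor(20, 40, 7, kmer=2)]
    frags = merge_diagonal_anchors(a)
    assert len(frags) == 2
    assert all(fr.weight == 7.0 for fr in frags)


# ---------------------------------------------------------------------------
# banded_one_gap_align
# ---------------------------------------------------------------------------


def one_free_gap_oracle(q: str, t: str, p: BandedAlignParams) -> float:
    """Unbanded DP allowing one contiguous free gap in the longer sequence."""
    if len(q) > len(t):
        q, t = t, q
    NEG = float("-inf")
    lq, lt = len(q), len(t)
    A = np.full((lq + 1, lt + 1), NEG)  # free gap unused
    B = np.full((lq + 1, lt + 1), NEG)  # inside the free gap
    C = np.full((lq + 1, lt + 1), NEG)  # free gap closed
    A[0, 0] = 0.0
    for i in range(lq + 1):
        for j in range(lt + 1):
            if i > 0 and j > 0:
                m = p.match if q[i - 1] == t[j - 1] else p.mismatch
                A[i, j] = max(A[i, j], A[i - 1, j - 1] + m)
                C[i, j] = max(C[i, j], C[i - 1, j - 1] + m)
            if j > 0:
                A[i, j] = max(A[i, j], A[i, j - 1] - p.delta)
                B[i, j] = max(A[i, j - 1], B[i, j - 1])
                C[i, j] = max(C[i, j], C[i, j - 1] - p.delta, B[i, j])
            if i > 0:
                A[i, j] = max(A[i, j], A[i - 1, j] - p.delta)
                C[i, j] = max(C[i, j], C[i - 1, j] - p.delta)
    return max(A[lq, lt], B[lq, lt], C[lq, lt])


def test_identical_sequences_align_all_match(rng):
    p = BandedAlignParams(band=7)
    q = random_seq(rng, 120)
    score, ops = banded_one_gap_align(q, q, p)
    assert ops == [(120, "M")]
    assert score == pytest.approx(p.match * 120)


def test_long_insertion_becomes_one_free_deletion_run(rng):
    p = BandedAlignParams(band=10)
    q = random_seq(rng, 200)
    t = q[:100] + random_seq(rng, 100) + q[100:]
    score, ops = banded_one_gap_align(q, t, p)
    big = [(n, op) for n, op in ops if op == "D" and n >= 50]
    assert len(big) == 1 and abs(big[0][0] - 100) <= 10
    assert cigar_spans(ops) == (len(q), len(t))


def test_query_side_insertion_transposes_to_i_ops(rng):
    p = BandedAlignParams(band=10)
    t = random_seq(rng, 200)
    q = t[:80] + random_seq(rng, 60) + t[80:]
    score, ops = banded_one_gap_align(q, t, p)
    big = [(n, op) for n, op in ops if op == "I" and n >= 40]
    assert len(big) == 1
    assert cigar_spans(ops) == (len(q), len(t))


def test_wide_band_matches_unbanded_one_free_gap_dp(rng):
    for _ in range(25):
        n = rng.randint(5, 70)
        q = random_seq(rng, n)
        t = list(q)
        for _ in range(rng.randint(0, 4)):
            i = rng.randrange(len(t))
            t[i] = rng.choice("ACGT")
        t = "".join(t)
        ins = random_seq(rng, rng.randint(1, 40))
        cut = rng.randrange(len(t) + 1)
        t = t[:cut] + ins + t[cut:]
        p = BandedAlignParams(band=200)
        score, ops = banded_one_gap_align(q, t, p)
        assert cigar_spans(ops) == (len(q), len(t))
        assert score == pytest.approx(one_free_gap_oracle(q, t, p), abs=1e-9)


# ---------------------------------------------------------------------------
# stitch_alignment
# ---------------------------------------------------------------------------


def _chain_over(frags):
    return chain_fragments(frags, GapFunction.log_cost())


def test_exact_substring_stitches_to_all_match(rng):
    ref = random_seq(rng, 800)
    q = ref[200:500]
    frag = Fragment(0, 200, 300, 500, 300.0)
    rec = stitch_alignment(q, ref, [frag], _chain_over([frag]))
    assert rec.pos == 200
    assert rec.cigar == [(300, "M")]
    assert rec.score == pytest.approx(2.0 * 300)


def test_deletion_read_carries_one_deletion_run(rng):
    ref = random_seq(rng, 1000)
    q = ref[100:400] + ref[500:800]  # 100-base deletion
    frags = [Fragment(0, 100, 300, 400, 300.0), Fragment(301, 501, 600, 800, 299.0)]
    rec = stitch_alignment(q, ref, frags, _chain_over(frags))
    dels = [n for n, op in rec.cigar if op == "D"]
    assert dels == [100]
    q_span, t_span = cigar_spans(rec.cigar)
    assert q_span == len(q)
    assert t_span == rec.target_end - rec.pos


def test_cigar_spans_are_consistent_on_random_stitches(rng):
    for _ in range(10):
        ref = random_seq(rng, 1200)
        a, b = sorted(rng.sample(range(100, 1100), 2))
        q = ref[a:b]
        frag = Fragment(0, a, b - a, b, float(b - a))
        rec = stitch_alignment(q, ref, [frag], _chain_over([frag]))
        q_span, t_span = cigar_spans(rec.cigar)
        assert q_span == len(q)
        assert t_span == rec.target_end - rec.pos


def test_inconsistent_chain_coordinates_raise():
    ref = "ACGT" * 100
    frags = [Fragment(0, 0, 50, 50, 50.0), Fragment(40, 100, 90, 150, 50.0)]  # overlaps in x
    from cgmap.chain import ChainResult

    fake = ChainResult(100.0, [0, 1], ["+", "+"])
    with pytest.raises(ValueError):
        stitch_alignment(ref[:200], ref, frags, fake)
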