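"""Forward concave-gap chaining: block structure, subproblems, chainers."""

from __future__ import annotations

import math
import random
from bisect import bisect_left

import pytest

from cgmap.chain import (
    NEG_INF,
    BlockStructure,
    Fragment,
    GapFunction,
    OpCounter,
    build_subproblems,
    chain_fragments,
    enumerate_optimal_chains,
    naive_chain,
)
from cgmap.chain import WORKED_EXAMPLE_CHAINS, WORKED_EXAMPLE_FRAGMENTS, WORKED_EXAMPLE_POINTS

from conftest import random_concave_gap, random_fragments


# ---------------------------------------------------------------------------
# GapFunction
# ---------------------------------------------------------------------------


def test_gap_function_rejects_convex_cost():
    with pytest.raises(ValueError):
        GapFunction(lambda d: d * d)


def test_gap_function_rejects_negative_cost():
    with pytest.raises(ValueError):
        GapFunction(lambda d: d - 5.0)


def test_default_log_gap_values():
    gap = GapFunction.log_cost()
    assert gap(0) == pytest.approx(1.0)
    assert gap(1) == pytest.approx(0.25 * math.log(2.0) + 1.0)
    assert gap(-3) == gap(3)  # penalty depends on |distance|


# ---------------------------------------------------------------------------
# Block structure: Omega(j) must equal the brute-force prefix optimum
# ---------------------------------------------------------------------------


def test_block_structure_matches_bruteforce_prefix_optimum(rng):
    """After any update sequence, query(j) equals a direct candidate scan."""
    for _ in range(400):
        m = rng.randint(1, 12)
        e_keys = sorted(rng.sample(range(-40, 40), m))
        gap = random_concave_gap(rng)
        bs = BlockStructure(e_keys, gap)
        cands = []
        for key in sorted(rng.sample(range(-45, 35), rng.randint(1, 10))):
            value = rng.uniform(0.0, 10.0)
            lo = bisect_left(e_keys, key)
            bs.update(key, value, lo, src=len(cands))
            cands.append((key, value, lo))
            for j in range(m):
                want = NEG_INF
                for k, v, l in cands:
                    if j >= l:
                        want = max(want, v - gap(e_keys[j] - k))
                got, _ = bs.query(j)
                if want == NEG_INF:
                    assert got == NEG_INF
                else:
                    assert got == pytest.approx(want, abs=1e-9)


def test_block_structure_sentinel_before_any_update():
    bs = BlockStructure([0, 5, 10], GapFunction.log_cost())
    assert bs.query(1) == (NEG_INF, None)


def test_block_structure_single_candidate():
    gap = GapFunction.log_cost()
    bs = BlockStructure([0, 5, 10], gap)
    bs.update(2, 7.0, 1, src=42)
    assert bs.query(0) == (NEG_INF, None)  # below the candidate's range
    val, src = bs.query(2)
    assert val == pytest.approx(7.0 - gap(10 - 2))
    assert src == 42


# ---------------------------------------------------------------------------
# Subproblem construction
# ---------------------------------------------------------------------------


def test_single_column_gives_one_leaf_with_empty_a_part():
    pts = [(3.0, 0.0, False, 0.0), (3.0, 5.0, True, 2.0)]
    subs, sa, sb = build_subproblems(pts, "column")
    assert len(subs) == 1
    assert subs[0].a_range is None and subs[0].d_keys == []


def test_membership_sizes_grow_logarithmically(rng):
    """Each point sits in O(log n) subproblems; total membership O(n log n)."""
    for n in (32, 128, 512):
        pts = []
        xs = rng.sample(range(10 * n), n)
        for i, x in enumerate(xs):
            pts.append((float(x), float(rng.randint(0, 10 * n)), i % 2 == 0, float(rng.randint(-50, 50))))
        subs, sa, sb = build_subproblems(pts, "column")
        per_point = [len(sa.get(i, [])) + len(sb.get(i, [])) for i in range(n)]
        assert max(per_point) <= math.ceil(math.log2(n)) + 1
        total = sum(per_point)
        assert total <= 2 * n * (math.log2(n) + 1)


def test_column_coverage_of_left_half_plane(rng):
    """A-parts of a start's SB subproblems tile exactly the columns left of it."""
    n = 40
    pts = []
    xs = rng.sample(range(500), n)
    for i, x in enumerate(xs):
        pts.append((float(x), float(rng.randint(0, 500)), i % 2 == 0, 0.0))
    subs, sa, sb = build_subproblems(pts, "column")
    col_values = sorted({p[0] for p in pts})
    rank = {v: i for i, v in enumerate(col_values)}
    for pid, p in enumerate(pts):
        if p[2]:  # end point
            continue
        covered: set[int] = set()
        for si, _ in sb.get(pid, []):
            a_range = subs[si].a_range
            if a_range is None:
                continue
            for r in range(a_range[0], a_range[1] + 1):
                assert r not in covered  # disjoint
                covered.add(r)
        assert covered == set(range(rank[p[0]]))


# ---------------------------------------------------------------------------
# The worked 12-point example
# ---------------------------------------------------------------------------


def test_worked_example_optimal_value_is_2_8():
    gap = GapFunction.log_cost(0.25, 1.0)
    res = chain_fragments(WORKED_EXAMPLE_FRAGMENTS, gap)
    assert round(res.score, 1) == 2.8


def test_worked_example_has_exactly_three_co_optimal_chains():
    gap = GapFunction.log_cost(0.25, 1.0)
    score, chains = enumerate_optimal_chains(WORKED_EXAMPLE_FRAGMENTS, gap)
    assert round(score, 1) == 2.8
    as_points = {
        tuple(p for frag in c for p in WORKED_EXAMPLE_POINTS[frag]) for c in chains
    }
    assert as_points == set(WORKED_EXAMPLE_CHAINS)
    assert naive_chain(WORKED_EXAMPLE_FRAGMENTS, gap, count_co_optimal=True).co_optimal_count == 3


# ---------------------------------------------------------------------------
# Chainers
# ---------------------------------------------------------------------------


def test_single_fragment_chain_is_its_weight():
    res = chain_fragments([Fragment(0, 0, 5, 5, 3.5)], GapFunction.log_cost())
    assert res.score == pytest.approx(3.5)
    assert res.fragments == [0]


def test_empty_input_yields_empty_chain():
    res = naive_chain([], GapFunction.log_cost())
    assert res.score == 0.0 and res.fragments == []
    res = chain_fragments([], GapFunction.log_cost())
    assert res.score == 0.0 and res.fragments == []


def test_unchainable_fragments_pick_best_singleton():
    # neither is above-right of the other
    frs = [Fragment(0, 10, 5, 15, 2.0), Fragment(6, 0, 11, 5, 3.0)]
    res = naive_chain(frs, GapFunction.log_cost())
    assert res.score == pytest.approx(3.0)
    assert res.fragments == [1]


def test_naive_chain_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        frs = random_fragments(rng, rng.randint(1, 8), span=60, size=12)
        gap = random_concave_gap(rng)
        want, chains = enumerate_optimal_chains(frs, gap)
        got = naive_chain(frs, gap, count_co_optimal=True)
        assert got.score == pytest.approx(want, abs=1e-6)
        assert got.co_optimal_count == len(chains)


def test_divide_and_conquer_matches_naive_on_random_instances(rng):
    for _ in range(150):
        frs = random_fragments(rng, rng.randint(1, 80), allow_degenerate=True)
        gap = random_concave_gap(rng)
        fast = chain_fragments(frs, gap)
        slow = naive_chain(frs, gap)
        assert fast.score == pytest.approx(slow.score, abs=1e-7)
        # returned chain must actually evaluate to the reported score
        _assert_chain_scores(frs, fast, gap)


def _assert_chain_scores(frs, res, gap):
    total = 0.0
    for i, fi in enumerate(res.fragments):
        total += frs[fi].weight
        if i:
            prev = frs[res.fragments[i - 1]]
            cur = frs[fi]
            assert prev.xe < cur.xs and prev.ye < cur.ys
            total -= gap(prev.f_end - cur.f_start)
    assert total == pytest.approx(res.score, abs=1e-7)


def test_chain_tie_break_is_deterministic():
    # two identical fragments: smallest index wins
    frs = [Fragment(0, 0, 5, 5, 2.0), Fragment(0, 0, 5, 5, 2.0)]
    res = chain_fragments(frs, GapFunction.log_cost())
    assert res.fragments == [0]


def test_operation_count_scales_as_n_log_squared():
    gap = GapFunction.log_cost()
    rng = random.Random(3)
    ratios = []
    for p in (7, 9, 11):
        n = 2 ** p
        frs = []
        for _ in range(n):
            xs = rng.randint(0, 50 * n)
            ys = rng.randint(0, 50 * n)
            d = rng.randint(5, 30)
            frs.append(Fragment(xs, ys, xs + d, ys + d, float(d)))
        cnt = OpCounter()
        chain_fragments(frs, gap, counter=cnt)
        ops = cnt.updates + cnt.queries + cnt.steps
        ratios.append(ops / (n * math.log2(n) ** 2))
    assert max(ratios) / min(ratios) < 2.0


# ---------------------------------------------------------------------------
# Property-based invariances
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def _fragment_lists(draw):
    n = draw(st.integers(1, 12))
    frs = []
    for _ in range(n):
        xs = draw(st.integers(0, 80))
        ys = draw(st.integers(0, 80))
        dx = draw(st.integers(0, 10))
        dy = draw(st.integers(0, 10))
        w = draw(st.floats(0.5, 5.0, allow_nan=False))
        frs.append(Fragment(xs, ys, xs + dx, ys + dy, w))
    return frs


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_fragment_lists())
def test_chain_score_matches_oracle_property(frs):
    gap = GapFunction.log_cost()
    assert chain_fragments(frs, gap).score == pytest.approx(naive_chain(frs, gap).score, abs=1e-7)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(_fragment_lists(), st.integers(-50, 50), st.integers(-50, 50))
def test_chain_score_is_translation_invariant(frs, dx, dy):
    """Shifting every fragment rigidly does not change the optimum."""
    gap = GapFunction.log_cost()
    shifted = [Fragment(f.xs + dx, f.ys + dy, f.xe + dx, f.ye + dy, f.weight) for f in frs]
    assert chain_fragments(shifted, gap).score == pytest.approx(
        chain_fragments(frs, gap).score, abs=1e-7
    )
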