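"""Exact fragment chaining under a concave gap cost (CG-SDP).

Chaining selects an ordered subset of weighted fragments on the query x
target plane that maximises total fragment weight minus a concave penalty
on the forward-diagonal jump between consecutive fragments.  A naive
dynamic program is quadratic in the number of fragments; here the search
for the best predecessor of each fragment is decomposed into O(log n)
column and row subproblems per point, each solved with an online block
structure that exploits concavity, for an O(n log^2 n) total.

The module exposes:

* :class:`Fragment` and :class:`GapFunction` - the problem inputs.
* :func:`chain_fragments` - the divide-and-conquer chainer.
* :func:`naive_chain` - the quadratic reference dynamic program.
* :func:`enumerate_optimal_chains` - exhaustive tied traceback, used to
  count co-optimal chains on small instances.
* :func:`build_subproblems`, :class:`BlockStructure` - the internals,
  exported so their contracts can be tested directly.

Scores are floats; ties are detected with a relative tolerance of 1e-9.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "Fragment",
    "GapFunction",
    "ChainResult",
    "Subproblem",
    "BlockStructure",
    "OpCounter",
    "build_subproblems",
    "chain_fragments",
    "naive_chain",
    "enumerate_optimal_chains",
]

TIE_TOL = 1e-9
NEG_INF = float("-inf")


def _close(a: float, b: float, tol: float = TIE_TOL) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


# ---------------------------------------------------------------------------
# Problem inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    """A weighted box on the query (x) x target (y) plane.

    ``(xs, ys)`` is the lower-left start point and ``(xe, ye)`` the
    upper-right end point; ``weight`` is the match bonus earned by
    including the fragment in a chain.  Minimizer fragments have their
    end point a fixed distance up the diagonal from the start;
    super-fragments built from fine clusters need not.

    Two further oriented points support chaining in the reverse
    direction (inversions): the upper-left start ``s2 = (xs, ye)`` and
    the lower-right end ``e2 = (xe, ys)``.
    """

    xs: float
    ys: float
    xe: float
    ye: float
    weight: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.xe < self.xs or self.ye < self.ys:
            raise ValueError("fragment end point must not precede its start point")
        if self.weight <= 0:
            raise ValueError("fragment weight must be positive")

    # forward-orientation chaining points
    @property
    def s1(self) -> tuple[float, float]:
        return (self.xs, self.ys)

    @property
    def e1(self) -> tuple[float, float]:
        return (self.xe, self.ye)

    # reverse-orientation chaining points
    @property
    def s2(self) -> tuple[float, float]:
        return (self.xs, self.ye)

    @property
    def e2(self) -> tuple[float, float]:
        return (self.xe, self.ys)

    @property
    def f_start(self) -> float:
        """Forward diagonal of the start point (y - x)."""
        return self.ys - self.xs

    @property
    def f_end(self) -> float:
        return self.ye - self.xe

    @property
    def r_start2(self) -> float:
        """Reverse diagonal (x + y) of the reverse-orientation start."""
        return self.xs + self.ye

    @property
    def r_end2(self) -> float:
        return self.xe + self.ys


class GapFunction:
    """A concave, non-negative penalty on diagonal distance.

    The default form is ``a * ln(d + 1) + b``.  Concavity (non-increasing
    increments) is validated on a sampled range at construction, since the
    chaining algorithm's correctness depends on it.
    """

    def __init__(
        self,
        fn: Callable[[float], float],
        a: float | None = None,
        b: float | None = None,
        check_range: int = 256,
    ) -> None:
        self._fn = fn
        self.a = a
        self.b = b
        self._validate(check_range)

    @classmethod
    def log_cost(cls, a: float = 0.25, b: float = 1.0) -> "GapFunction":
        return cls(lambda d: a * math.log(d + 1.0) + b, a=a, b=b)

    @classmethod
    def sqrt_cost(cls, a: float = 0.5, b: float = 1.0) -> "GapFunction":
        return cls(lambda d: a * math.sqrt(d) + b, a=a, b=b)

    @classmethod
    def linear_cost(cls, a: float = 0.1, b: float = 1.0) -> "GapFunction":
        return cls(lambda d: a * d + b, a=a, b=b)

    def _validate(self, n: int) -> None:
        prev_val = self._fn(0)
        if prev_val < 0:
            raise ValueError("gap cost must be non-negative")
        prev_inc = float("inf")
        for d in range(1, n):
            val = self._fn(d)
            if val < 0:
                raise ValueError("gap cost must be non-negative")
            inc = val - prev_val
            if inc > prev_inc + 1e-12:
                raise ValueError("gap cost is not concave")
            prev_inc = inc
            prev_val = val

    def __call__(self, d: float) -> float:
        return self._fn(abs(d))


@dataclass
class ChainResult:
    """An optimal chain: its score, member fragments and orientations."""

    score: float
    fragments: list[int]
    orientations: list[str]
    co_optimal_count: int | None = None


# ---------------------------------------------------------------------------
# Block structure: online concave maximisation over diagonals
# ---------------------------------------------------------------------------


class OpCounter:
    """Counts Update/query calls and their internal binary-search steps."""

    __slots__ = ("updates", "queries", "steps")

    def __init__(self) -> None:
        self.updates = 0
        self.queries = 0
        self.steps = 0


@dataclass
class _Candidate:
    key: float  # transformed diagonal of the predecessor endpoint
    value: float  # chain score at that endpoint
    src: int  # endpoint id for traceback


class BlockStructure:
    """Maintains, per reachable diagonal, the best chaining value so far.

    Positions ``0..m-1`` correspond to the (transformed) start-point
    diagonals ``E_I`` of one subproblem, in increasing key order.
    Candidates are predecessor diagonals from ``D_I``, supplied in
    increasing key order, each at most once (the ``E_L`` discipline of the
    caller guarantees this).  Concavity of the gap cost makes the set of
    positions where a new candidate beats the incumbent structure a
    contiguous prefix of its validity range, so an update is a walk with
    binary searches: O(log m) amortised.  ``query(j)`` reconstructs
    ``E_V[j]`` together with the winning candidate.
    """

    def __init__(
        self,
        e_keys: Sequence[float],
        gap: GapFunction,
        counter: OpCounter | None = None,
    ) -> None:
        self.e_keys = e_keys
        self.gap = gap
        self.counter = counter
        # parallel lists: block i covers positions [starts[i], starts[i+1])
        self._starts: list[int] = []
        self._cands: list[_Candidate] = []
        self._last_key: float | None = None

    def _score(self, cand: _Candidate, j: int) -> float:
        return cand.value - self.gap(self.e_keys[j] - cand.key)

    def update(self, key: float, value: float, lo: int, src: int) -> None:
        """Insert predecessor diagonal ``key`` with chain score ``value``.

        ``lo`` is the first position the candidate may legally precede.
        """
        if self.counter is not None:
            self.counter.updates += 1
        if self._last_key is not None and key < self._last_key:
            raise AssertionError("candidates must arrive in increasing key order")
        self._last_key = key
        m = len(self.e_keys)
        if lo >= m:
            return
        cand = _Candidate(key, value, src)
        starts, cands = self._starts, self._cands
        if not starts:
            starts.append(lo)
            cands.append(cand)
            return
        # Concavity makes the new candidate's winning region a contiguous
        # prefix [lo, c) of its validity range.  Phase 1 finds c by walking
        # blocks rightward from the one covering lo, binary-searching the
        # crossover inside the block where the incumbent first wins back.
        bi = bisect_right(starts, lo) - 1
        if self.counter is not None:
            self.counter.steps += max(1, len(starts).bit_length())
        if bi < 0:
            bi = 0
        c = m  # first position where an incumbent beats the new candidate
        while bi < len(starts):
            block_lo = max(lo, starts[bi])
            block_hi = starts[bi + 1] - 1 if bi + 1 < len(starts) else m - 1
            inc = cands[bi]
            if self._score(cand, block_lo) <= self._score(inc, block_lo):
                c = block_lo
                break
            if self._score(cand, block_hi) > self._score(inc, block_hi):
                bi += 1  # whole block beaten; keep walking
                continue
            a, b = block_lo, block_hi  # new wins at a, incumbent at b
            while b - a > 1:
                mid = (a + b) // 2
                if self._score(cand, mid) > self._score(inc, mid):
                    a = mid
                else:
                    b = mid
                if self.counter is not None:
                    self.counter.steps += 1
            c = b
            break
        if c <= lo:
            return  # wins nothing
        # Phase 2: rebuild — blocks starting in [lo, c) are evicted, the
        # incumbent covering c (if any) resumes there, later blocks stand.
        keep_left = bisect_left(starts, lo)
        if c < m:
            inc_at_c = cands[bisect_right(starts, c) - 1]
            tail_from = bisect_right(starts, c)
            self._starts = starts[:keep_left] + [lo, c] + starts[tail_from:]
            self._cands = cands[:keep_left] + [cand, inc_at_c] + cands[tail_from:]
        else:
            self._starts = starts[:keep_left] + [lo]
            self._cands = cands[:keep_left] + [cand]

    def query(self, j: int) -> tuple[float, int | None]:
        """Best chaining value for position ``j`` and the endpoint achieving it."""
        if self.counter is not None:
            self.counter.queries += 1
            self.counter.steps += max(1, len(self._starts).bit_length())
        if not self._starts or j < self._starts[0]:
            return NEG_INF, None
        bi = bisect_right(self._starts, j) - 1
        cand = self._cands[bi]
        return self._score(cand, j), cand.src


# ---------------------------------------------------------------------------
# Subproblem construction (divide and conquer over columns / rows)
# ---------------------------------------------------------------------------


@dataclass
class Subproblem:
    """One column/row divide-and-conquer unit.

    The A-part holds end points (potential predecessors), the B-part
    start points.  ``d_keys``/``e_keys`` are the transformed diagonals
    (``D_I``/``E_I``) of those points in increasing key order;
    ``d_vals``/``d_src`` are ``D_V``/``D_P``; ``consumed`` is ``E_L + 1``,
    the number of predecessor diagonals already fed to the block
    structure.  Leaf subproblems (a single column/row) have an empty
    A-part.
    """

    orientation: str  # "column" | "row"
    a_range: tuple[int, int] | None  # rank interval of the A-part (None = leaf)
    b_range: tuple[int, int]
    d_keys: list[float] = field(default_factory=list)
    e_keys: list[float] = field(default_factory=list)
    d_vals: list[float] = field(default_factory=list)
    d_src: list[int | None] = field(default_factory=list)
    consumed: int = 0  # = E_L + 1
    blocks: BlockStructure | None = None
    strict: bool = False  # predecessor key must be strictly below the start key

    def lo_for(self, k: int) -> int:
        key = self.d_keys[k]
        if self.strict:
            return bisect_right(self.e_keys, key)
        return bisect_left(self.e_keys, key)

    def frontier(self, key: float) -> int:
        """Number of predecessor diagonals usable by a start on ``key``."""
        if self.strict:
            return bisect_left(self.d_keys, key)
        return bisect_right(self.d_keys, key)


@dataclass(frozen=True)
class _Point:
    x: float
    y: float
    is_end: bool
    frag: int
    entry: str  # "s1" | "e1" | "s2" | "e2"
    key: float  # transformed diagonal for the family it belongs to


class _Family:
    """One of the (up to four) subproblem families of a chaining pass.

    A family fixes: the splitting axis (columns = x, rows = y), which half
    of the axis the A-part occupies, the diagonal transform, and whether
    the predecessor-key comparison is strict.  The transforms are chosen
    so that in every family the legal-predecessor condition reads
    ``key(end) <= key(start)`` (or ``<`` when strict), keys increase along
    ``D_I``/``E_I``, and ``|key(end) - key(start)|`` equals the diagonal
    distance fed to the gap cost.
    """

    def __init__(
        self,
        name: str,
        axis: str,  # "x" | "y"
        a_side: str,  # "low" | "high"
        strict: bool,
        gap: GapFunction,
        counter: OpCounter | None,
    ) -> None:
        self.name = name
        self.axis = axis
        self.a_side = a_side
        self.strict = strict
        self.gap = gap
        self.counter = counter
        self.subproblems: list[Subproblem] = []
        self.sa: dict[int, list[tuple[int, int]]] = {}  # point id -> [(sub, k)]
        self.sb: dict[int, list[tuple[int, int]]] = {}  # point id -> [(sub, j)]

    def build(self, points: Sequence[_Point], ids: Sequence[int]) -> None:
        coord = (lambda p: p.x) if self.axis == "x" else (lambda p: p.y)
        values = sorted({coord(p) for p in points})
        rank = {v: i for i, v in enumerate(values)}
        by_rank: dict[int, list[int]] = {}
        for pid, p in zip(ids, points):
            by_rank.setdefault(rank[coord(p)], []).append(pid)
        self._points = {pid: p for pid, p in zip(ids, points)}
        if values:
            self._recurse(0, len(values) - 1, by_rank)

    def _recurse(self, s: int, e: int, by_rank: dict[int, list[int]]) -> None:
        if s == e:
            # leaf: empty A-part, nothing to chain within a single column/row
            self.subproblems.append(
                Subproblem(
                    orientation="column" if self.axis == "x" else "row",
                    a_range=None,
                    b_range=(s, e),
                    strict=self.strict,
                )
            )
            return
        mid = (s + e) // 2
        if self.a_side == "low":
            a_lo, a_hi, b_lo, b_hi = s, mid, mid + 1, e
        else:
            a_lo, a_hi, b_lo, b_hi = mid + 1, e, s, mid
        a_pts = [
            pid
            for r in range(a_lo, a_hi + 1)
            for pid in by_rank.get(r, ())
            if self._points[pid].is_end
        ]
        b_pts = [
            pid
            for r in range(b_lo, b_hi + 1)
            for pid in by_rank.get(r, ())
            if not self._points[pid].is_end
        ]
        sub = Subproblem(
            orientation="column" if self.axis == "x" else "row",
            a_range=(a_lo, a_hi),
            b_range=(b_lo, b_hi),
            strict=self.strict,
        )
        sub.d_keys = sorted({self._points[pid].key for pid in a_pts})
        sub.e_keys = sorted({self._points[pid].key for pid in b_pts})
        sub.d_vals = [NEG_INF] * len(sub.d_keys)
        sub.d_src = [None] * len(sub.d_keys)
        if sub.d_keys and sub.e_keys:
            sub.blocks = BlockStructure(sub.e_keys, self.gap, self.counter)
        si = len(self.subproblems)
        self.subproblems.append(sub)
        if sub.d_keys:
            for pid in a_pts:
                k = bisect_left(sub.d_keys, self._points[pid].key)
                self.sa.setdefault(pid, []).append((si, k))
        if sub.e_keys:
            for pid in b_pts:
                j = bisect_left(sub.e_keys, self._points[pid].key)
                self.sb.setdefault(pid, []).append((si, j))
        self._recurse(s, mid, by_rank)
        self._recurse(mid + 1, e, by_rank)

    # -- solving ------------------------------------------------------------

    def query_start(self, pid: int, key: float) -> tuple[float, int | None]:
        """Best predecessor value for start point ``pid`` over this family."""
        best, src = NEG_INF, None
        for si, j in self.sb.get(pid, ()):
            sub = self.subproblems[si]
            if sub.blocks is None:
                continue
            c = sub.frontier(key)
            while sub.consumed < c:
                k = sub.consumed
                val = sub.d_vals[k]
                if val == NEG_INF:
                    raise AssertionError(
                        "predecessor diagonal consumed before its endpoint was solved"
                    )
                sub.blocks.update(sub.d_keys[k], val, sub.lo_for(k), sub.d_src[k])
                sub.consumed += 1
            val, vsrc = sub.blocks.query(j)
            if val > best + TIE_TOL * max(1.0, abs(val), abs(best)) or (
                _close(val, best) and vsrc is not None and (src is None or vsrc < src)
            ):
                best, src = val, vsrc
        return best, src

    def record_end(self, pid: int, score: float) -> None:
        for si, k in self.sa.get(pid, ()):
            sub = self.subproblems[si]
            if score > sub.d_vals[k]:
                sub.d_vals[k] = score
                sub.d_src[k] = pid


def build_subproblems(
    points: Sequence[tuple[float, float, bool, float]],
    orientation: str,
    gap: GapFunction | None = None,
    strict: bool | None = None,
) -> tuple[list[Subproblem], dict[int, list[tuple[int, int]]], dict[int, list[tuple[int, int]]]]:
    """Build the column or row subproblems for a set of points.

    ``points`` are ``(x, y, is_end, diagonal_key)`` tuples, already
    expressed in the family's transformed key.  Returns the subproblems
    plus the per-point SA (A-part) and SB (B-part) membership lists.
    Exposed mainly so the decomposition's coverage and size invariants
    can be tested in isolation.
    """
    if orientation not in ("column", "row"):
        raise ValueError("orientation must be 'column' or 'row'")
    if gap is None:
        gap = GapFunction.log_cost()
    if strict is None:
        strict = orientation == "row"
    fam = _Family(
        orientation,
        axis="x" if orientation == "column" else "y",
        a_side="low",
        strict=strict,
        gap=gap,
        counter=None,
    )
    pts = [_Point(x, y, is_end, i, "e1" if is_end else "s1", key) for i, (x, y, is_end, key) in enumerate(points)]
    fam.build(pts, list(range(len(pts))))
    return fam.subproblems, fam.sa, fam.sb


# ---------------------------------------------------------------------------
# The chainers
# ---------------------------------------------------------------------------


def _sorted_point_order(points: list[_Point], ids: list[int]) -> list[int]:
    # starts before ends on coordinate ties: a start at the same point as
    # an end may not chain to it (strict above-right is required)
    order = sorted(range(len(points)), key=lambda i: (points[i].x, points[i].y, points[i].is_end))
    return [ids[i] for i in order]


def chain_fragments(
    fragments: Sequence[Fragment],
    gap: GapFunction,
    counter: OpCounter | None = None,
) -> ChainResult:
    """Optimal forward chain of ``fragments`` under concave gap cost.

    Points (one start and one end per fragment) are processed in
    Cartesian (x, then y) order.  A start point takes the best value over
    the column subproblems (predecessor endpoints to its left on a
    smaller-or-equal forward diagonal) and the row subproblems
    (predecessors below it on a strictly larger forward diagonal), or 0
    when no endpoint precedes it.  An end point scores its fragment's
    start value plus the match bonus and publishes it to the subproblems
    holding it in an A-part.
    """
    if not fragments:
        return ChainResult(0.0, [], [])
    pts: list[_Point] = []
    for i, fr in enumerate(fragments):
        pts.append(_Point(fr.xs, fr.ys, False, i, "s1", fr.f_start))
        pts.append(_Point(fr.xe, fr.ye, True, i, "e1", fr.f_end))
    col = _Family("column-1", "x", "low", strict=False, gap=gap, counter=counter)
    row = _Family("row-1", "y", "low", strict=True, gap=gap, counter=counter)
    ids = list(range(len(pts)))
    col_pts = pts
    row_pts = [
        _Point(p.x, p.y, p.is_end, p.frag, p.entry, -p.key) for p in pts
    ]  # rows need the larger-diagonal predecessors: negate so keys increase
    col.build(col_pts, ids)
    row.build(row_pts, ids)

    order = _sorted_point_order(pts, ids)
    start_val: dict[int, float] = {}
    start_pred: dict[int, int | None] = {}
    frag_score: dict[int, float] = {}
    best_end_val, best_end_frag = NEG_INF, None
    for pid in order:
        p = pts[pid]
        if not p.is_end:
            vc, sc = col.query_start(pid, p.key)
            vr, sr = row.query_start(pid, -p.key)
            val, src = vc, sc
            if vr > val + TIE_TOL * max(1.0, abs(vr), abs(val)) or (
                _close(vr, val) and sr is not None and (src is None or pts[sr].frag < pts[src].frag)
            ):
                val, src = vr, sr
            if val < 0.0:
                val, src = 0.0, None
            start_val[p.frag] = val
            start_pred[p.frag] = None if src is None else pts[src].frag
        else:
            score = start_val[p.frag] + fragments[p.frag].weight
            frag_score[p.frag] = score
            col.record_end(pid, score)
            row.record_end(pid, score)
            if score > best_end_val + TIE_TOL * max(1.0, abs(score), abs(best_end_val)) or (
                _close(score, best_end_val) and (best_end_frag is None or p.frag < best_end_frag)
            ):
                best_end_val, best_end_frag = score, p.frag

    chain: list[int] = []
    cur = best_end_frag
    while cur is not None:
        chain.append(cur)
        cur = start_pred[cur]
    chain.reverse()
    return ChainResult(best_end_val, chain, ["+"] * len(chain))


def naive_chain(
    fragments: Sequence[Fragment],
    gap: GapFunction,
    count_co_optimal: bool = False,
) -> ChainResult:
    """Quadratic reference chainer: scan all predecessor pairs directly."""
    n = len(fragments)
    if n == 0:
        return ChainResult(0.0, [], [], co_optimal_count=0 if count_co_optimal else None)
    order = sorted(range(n), key=lambda i: (fragments[i].xs, fragments[i].ys))
    val = [0.0] * n
    pred: list[int | None] = [None] * n
    nways = [1] * n  # optimal chains ending at fragment i
    for idx, i in enumerate(order):
        fi = fragments[i]
        best, bsrc = 0.0, None
        ways = 1  # the chain that starts fresh at i
        for j in order[:idx]:
            fj = fragments[j]
            if fj.xe < fi.xs and fj.ye < fi.ys:
                cand = val[j] - gap(fj.f_end - fi.f_start)
                if cand > best + TIE_TOL * max(1.0, abs(cand), abs(best)):
                    best, bsrc, ways = cand, j, nways[j]
                elif _close(cand, best):
                    ways = ways + nways[j] if bsrc is not None or cand > 0 or _close(cand, 0.0) else ways
                    if bsrc is None or j < bsrc:
                        bsrc = j if not _close(cand, 0.0) or cand >= 0 else bsrc
        val[i] = best + fi.weight
        pred[i] = bsrc
        nways[i] = ways
    best_i = max(range(n), key=lambda i: (val[i], -i))
    # deterministic tie-break on the reported chain: smallest fragment index
    for i in range(n):
        if _close(val[i], val[best_i]) and i < best_i:
            best_i = i
    chain: list[int] = []
    cur: int | None = best_i
    while cur is not None:
        chain.append(cur)
        cur = pred[cur]
    chain.reverse()
    co = None
    if count_co_optimal:
        opt = val[best_i]
        co = sum(nways[i] for i in range(n) if _close(val[i], opt))
    return ChainResult(val[best_i], chain, ["+"] * len(chain), co_optimal_count=co)


def enumerate_optimal_chains(
    fragments: Sequence[Fragment],
    gap: GapFunction,
    tol: float = 1e-6,
) -> tuple[float, list[list[int]]]:
    """Exhaustively enumerate all optimal chains (small instances only).

    Depth-first search over the chainability DAG; returns the optimal
    score and every chain achieving it within ``tol``.
    """
    n = len(fragments)
    if n == 0:
        return 0.0, []
    best_score = NEG_INF
    chains: list[list[int]] = []

    def extend(chain: list[int], score: float) -> None:
        nonlocal best_score, chains
        if score > best_score + tol:
            best_score = score
            chains = [list(chain)]
        elif abs(score - best_score) <= tol:
            chains.append(list(chain))
        last = fragments[chain[-1]]
        for j in range(n):
            fj = fragments[j]
            if last.xe < fj.xs and last.ye < fj.ys:
                extend(chain + [j], score + fj.weight - gap(last.f_end - fj.f_start))

    for i in range(n):
        extend([i], fragments[i].weight)
    # deduplicate (identical chains can be reached once only, but be safe)
    uniq = []
    seen = set()
    for c in chains:
        t = tuple(c)
        if t not in seen:
            seen.add(t)
            uniq.append(c)
    return best_score, uniq


# ---------------------------------------------------------------------------
# The worked 12-point example
# ---------------------------------------------------------------------------

#: Six fragments whose twelve start/end points, numbered in Cartesian
#: processing order, form the standard worked example for this chainer:
#: with match bonus 2 and gap cost 0.25*ln(d+1)+1 the optimal chain value
#: is 2.83 (printed as 2.8) and exactly three chains achieve it.
WORKED_EXAMPLE_FRAGMENTS: tuple[Fragment, ...] = (
    Fragment(0, 0, 2, 2, 2.0),  # points 1 (start), 2 (end); diagonal 0
    Fragment(3, 4, 6, 7, 2.0),  # points 3, 6; diagonal +1
    Fragment(4, 1, 7, 4, 2.0),  # points 4, 8; diagonal -3
    Fragment(5, 4, 8, 7, 2.0),  # points 5, 9; diagonal -1
    Fragment(7, 1, 10, 4, 2.0),  # points 7, 10; diagonal -6
    Fragment(11, 6, 13, 8, 2.0),  # points 11, 12; diagonal -5
)

#: The three co-optimal chains of the worked example, as point numbers.
WORKED_EXAMPLE_CHAINS: tuple[tuple[int, ...], ...] = (
    (1, 2, 3, 6),
    (1, 2, 5, 9),
    (7, 10, 11, 12),
)

#: Point numbers (Cartesian order) for each fragment: (start, end).
WORKED_EXAMPLE_POINTS: tuple[tuple[int, int], ...] = (
    (1, 2),
    (3, 6),
    (4, 8),
    (5, 9),
    (7, 10),
    (11, 12),
)
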