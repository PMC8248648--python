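"""Inversion-aware fragment chaining.

Extends concave-gap sparse DP chaining so that a fragment may also be
chained in the *reverse* direction: besides the lower-left start ``s1``
and upper-right end ``e1``, each fragment contributes an upper-left
start ``s2 = (xs, ye)`` and a lower-right end ``e2 = (xe, ys)``.  A
reverse link chains ``s2`` of a fragment to ``e2`` of a predecessor that
is to the left and *above* (``x_e2 < x_s2`` and ``y_e2 > y_s2``), with a
concave penalty on the reverse-diagonal (x + y) difference.  This lets
an optimal chain descend through a block of anti-diagonal fragments — a
sequence inversion — and climb back out, without splitting the
alignment.

Four subproblem families are used: column-1/row-1 over ``s1``/``e1``
points keyed by forward diagonal, and column-2/row-2 over ``s2``/``e2``
points keyed by reverse diagonal.  All points are processed in one
Cartesian (x, then y) sweep; a fragment's value is
``max(Score(s1), Score(s2)) + weight`` and is published through both of
its end points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chain import (
    NEG_INF,
    TIE_TOL,
    ChainResult,
    Fragment,
    GapFunction,
    OpCounter,
    _close,
    _Family,
    _Point,
)

__all__ = [
    "InversionChainConfig",
    "chain_with_inversions",
    "naive_chain_with_inversions",
]


@dataclass
class InversionChainConfig:
    """Gap model for inversion-aware chaining.

    ``gap_fwd`` penalises forward-diagonal jumps between forward links;
    ``gap_rev`` penalises reverse-diagonal jumps between reverse links.
    ``inversion_open`` is a constant added to every reverse link, letting
    a pipeline discourage spurious strand flips (0 keeps the model
    exactly as the chaining recurrence states it).
    """

    gap_fwd: GapFunction
    gap_rev: GapFunction
    inversion_open: float = 0.0


def _rev_gap(config: InversionChainConfig) -> GapFunction:
    if config.inversion_open == 0.0:
        return config.gap_rev
    base = config.gap_rev
    return GapFunction(lambda d: base(d) + config.inversion_open)


def chain_with_inversions(
    fragments: Sequence[Fragment],
    config: InversionChainConfig,
    counter: OpCounter | None = None,
) -> ChainResult:
    """Optimal chain allowing both forward and reverse links.

    Returns the chain in traversal order with a per-fragment orientation
    label: ``"+"`` when the fragment was entered by a forward link (or
    starts the chain), ``"-"`` when entered by a reverse link.
    """
    if not fragments:
        return ChainResult(0.0, [], [])
    gap_rev = _rev_gap(config)

    pts: list[_Point] = []
    for i, fr in enumerate(fragments):
        pts.append(_Point(fr.xs, fr.ys, False, i, "s1", fr.f_start))
        pts.append(_Point(fr.xe, fr.ye, True, i, "e1", fr.f_end))
        pts.append(_Point(fr.xs, fr.ye, False, i, "s2", fr.r_start2))
        pts.append(_Point(fr.xe, fr.ys, True, i, "e2", fr.r_end2))
    ids = list(range(len(pts)))
    id1 = [pid for pid in ids if pts[pid].entry in ("s1", "e1")]
    id2 = [pid for pid in ids if pts[pid].entry in ("s2", "e2")]

    # Forward families: legality is "end strictly below-left of start".
    # Column split guarantees x; the key condition f_end <= f_start then
    # forces y.  Row split guarantees y; f_end > f_start forces x
    # (strict, keys negated so they still increase along D_I/E_I).
    col1 = _Family("column-1", "x", "low", strict=False, gap=config.gap_fwd, counter=counter)
    row1 = _Family("row-1", "y", "low", strict=True, gap=config.gap_fwd, counter=counter)
    col1.build([pts[pid] for pid in id1], id1)
    row1.build(
        [_Point(pts[pid].x, pts[pid].y, pts[pid].is_end, pts[pid].frag, pts[pid].entry, -pts[pid].key) for pid in id1],
        id1,
    )
    # Reverse families: legality is "end left of and above the start".
    # Column-2 guarantees x; r_end >= r_start then forces y (keys negated
    # to keep the <= convention).  Row-2 puts the A-part in the *upper*
    # rows, guaranteeing y; r_end <= r_start forces x.
    col2 = _Family("column-2", "x", "low", strict=False, gap=gap_rev, counter=counter)
    row2 = _Family("row-2", "y", "high", strict=False, gap=gap_rev, counter=counter)
    col2.build(
        [_Point(pts[pid].x, pts[pid].y, pts[pid].is_end, pts[pid].frag, pts[pid].entry, -pts[pid].key) for pid in id2],
        id2,
    )
    row2.build([pts[pid] for pid in id2], id2)

    order = sorted(ids, key=lambda pid: (pts[pid].x, pts[pid].y, pts[pid].is_end))
    s_val: dict[tuple[int, str], float] = {}
    s_pred: dict[tuple[int, str], int | None] = {}
    start_pid = {(pts[pid].frag, pts[pid].entry): pid for pid in ids if not pts[pid].is_end}
    frag_score: dict[int, float] = {}
    best_val, best_frag = NEG_INF, None

    def solve_start(pid: int) -> None:
        p = pts[pid]
        if p.entry == "s1":
            vc, sc = col1.query_start(pid, p.key)
            vr, sr = row1.query_start(pid, -p.key)
        else:
            vc, sc = col2.query_start(pid, -p.key)
            vr, sr = row2.query_start(pid, p.key)
        val, src = vc, sc
        if vr > val + TIE_TOL * max(1.0, abs(vr), abs(val)) or (
            _close(vr, val) and sr is not None and (src is None or pts[sr].frag < pts[src].frag)
        ):
            val, src = vr, sr
        if val < 0.0:
            val, src = 0.0, None
        s_val[(p.frag, p.entry)] = val
        s_pred[(p.frag, p.entry)] = src

    for pid in order:
        p = pts[pid]
        if not p.is_end:
            if (p.frag, p.entry) not in s_val:
                solve_start(pid)
        else:
            if p.frag not in frag_score:
                # a zero-width fragment sweeps e2 before s2; everything s2
                # depends on lies at strictly smaller x, so solve it now
                for entry in ("s1", "s2"):
                    if (p.frag, entry) not in s_val:
                        solve_start(start_pid[(p.frag, entry)])
                v1 = s_val[(p.frag, "s1")]
                v2 = s_val[(p.frag, "s2")]
                frag_score[p.frag] = max(v1, v2) + fragments[p.frag].weight
            score = frag_score[p.frag]
            if p.entry == "e1":
                col1.record_end(pid, score)
                row1.record_end(pid, score)
            else:
                col2.record_end(pid, score)
                row2.record_end(pid, score)
            if score > best_val + TIE_TOL * max(1.0, abs(score), abs(best_val)) or (
                _close(score, best_val) and (best_frag is None or p.frag < best_frag)
            ):
                best_val, best_frag = score, p.frag

    # traceback: at each fragment pick the entry achieving its score
    chain: list[int] = []
    orients: list[str] = []
    cur = best_frag
    entry_used: str | None = None
    while cur is not None:
        chain.append(cur)
        v1 = s_val[(cur, "s1")]
        v2 = s_val[(cur, "s2")]
        use = "s1" if v1 >= v2 else "s2"
        orients.append("+" if use == "s1" else "-")
        src = s_pred[(cur, use)]
        cur = None if src is None else pts[src].frag
    chain.reverse()
    orients.reverse()
    # a fragment entered by a forward link but *followed* by nothing keeps
    # "+"; the label records how the chain arrived at the fragment
    return ChainResult(best_val, chain, orients)


def naive_chain_with_inversions(
    fragments: Sequence[Fragment],
    config: InversionChainConfig,
) -> ChainResult:
    """Quadratic oracle applying the forward and reverse link predicates."""
    n = len(fragments)
    if n == 0:
        return ChainResult(0.0, [], [])
    gap_rev = _rev_gap(config)
    order = sorted(range(n), key=lambda i: (fragments[i].xs, fragments[i].ys))
    val = [0.0] * n
    pred: list[int | None] = [None] * n
    orient = ["+"] * n  # orientation of the link INTO fragment i
    for idx, i in enumerate(order):
        fi = fragments[i]
        best, bsrc, bor = 0.0, None, "+"
        for j in order[:idx]:
            fj = fragments[j]
            # forward: e1(j) strictly below-left of s1(i)
            if fj.xe < fi.xs and fj.ye < fi.ys:
                cand = val[j] - config.gap_fwd(fj.f_end - fi.f_start)
                if cand > best + TIE_TOL * max(1.0, abs(cand), abs(best)) or (
                    _close(cand, best) and bsrc is not None and j < bsrc
                ):
                    best, bsrc, bor = cand, j, "+"
            # reverse: e2(j) left of and above s2(i)
            if fj.xe < fi.xs and fj.ys > fi.ye:
                cand = val[j] - gap_rev(fj.r_end2 - fi.r_start2)
                if cand > best + TIE_TOL * max(1.0, abs(cand), abs(best)) or (
                    _close(cand, best) and bsrc is not None and j < bsrc
                ):
                    best, bsrc, bor = cand, j, "-"
        val[i] = best + fi.weight
        pred[i] = bsrc
        orient[i] = bor
    best_i = 0
    for i in range(1, n):
        if val[i] > val[best_i] + TIE_TOL * max(1.0, abs(val[i]), abs(val[best_i])):
            best_i = i
    for i in range(n):
        if _close(val[i], val[best_i]) and i < best_i:
            best_i = i
    chain: list[int] = []
    orients: list[str] = []
    cur: int | None = best_i
    while cur is not None:
        chain.append(cur)
        orients.append(orient[cur] if pred[cur] is not None else "+")
        cur = pred[cur]
    chain.reverse()
    orients.reverse()
    return ChainResult(val[best_i], chain, orients)
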