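"""Alignment refinement: local anchors, diagonal merging, banded
alignment with one free gap, and stitching a chain into a CIGAR.

A coarse chain places the read; refinement produces base-level detail.
Local minimizer indexes (finer k and w) are cross-matched over the tiles
covered by the chain to yield dense anchors; same-diagonal runs are
merged into fragments; a second concave-gap chaining pass selects the
final anchor set; and the inter-anchor sequence is aligned with a
two-band dynamic program that allows a single large penalty-free gap —
the model for a structural variant between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chain import ChainResult, Fragment, GapFunction, chain_fragments
from .index import Anchor, LocalIndex, revcomp

__all__ = [
    "BandedAlignParams",
    "AlignmentRecord",
    "local_anchors",
    "merge_diagonal_anchors",
    "banded_one_gap_align",
    "stitch_alignment",
    "cigar_spans",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BandedAlignParams:
    """Scoring for banded alignment: match/mismatch, gap-per-base, band."""

    match: float = 2.0
    mismatch: float = -4.0
    delta: float = 3.0  # linear gap penalty per base
    band: int = 10
    max_junction: int = 50_000  # inter-anchor regions longer than this stay unaligned

    def __post_init__(self) -> None:
        if self.band < 1:
            raise ValueError("band must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def score(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


@dataclass
class AlignmentRecord:
    """One pairwise alignment, SAM/PAF serialisable.

    ``pos`` is the 0-based target start; CIGAR operations use M/I/D/S.
    """

    qname: str
    tname: str
    pos: int
    strand: str
    cigar: list[tuple[int, str]]
    score: float
    mapq: int = 0
    is_supplementary: bool = False
    query_length: int = 0
    seq: str = ""

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar) if self.cigar else "*"

    @property
    def query_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MI")

    @property
    def target_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MD")

    @property
    def target_end(self) -> int:
        return self.pos + self.target_span


def cigar_spans(cigar: Sequence[tuple[int, str]]) -> tuple[int, int]:
    """(query-consumed, target-consumed) base counts of a CIGAR."""
    q = sum(n for n, op in cigar if op in "MIS")
    t = sum(n for n, op in cigar if op in "MD")
    return q, t


def _coalesce(ops: list[tuple[int, str]]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for n, op in ops:
        if n == 0:
            continue
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return out


# ---------------------------------------------------------------------------
# Local anchoring and diagonal merging
# ---------------------------------------------------------------------------


def local_anchors(
    query: str,
    target: str,
    chain_anchors: Sequence[Anchor],
    q_index: LocalIndex,
    t_index: LocalIndex,
) -> list[Anchor]:
    """Fine-resolution anchors between the tile pairs a chain touches.

    For each consecutive pair of chained anchors (and the anchors
    themselves), the query and target tiles covering the spanned region
    are cross-matched at the local (k, w); each tile pair is compared at
    most once.  Anchors are reported in absolute coordinates, forward
    matches only (the caller orients reverse segments beforehand).
    """
    if q_index.params != t_index.params:
        raise ValueError("query and target local indexes must share parameters")
    k = q_index.params.k
    pairs: set[tuple[int, int]] = set()
    ordered = sorted(chain_anchors, key=lambda a: (a.x, a.y))
    for a, b in zip(ordered, ordered[1:] if len(ordered) > 1 else ordered):
        q_lo, q_hi = a.x, max(a.x + a.k, b.x + b.k)
        t_lo, t_hi = min(a.y, b.y), max(a.y + a.k, b.y + b.k)
        for qt in q_index.tile_range(q_lo, q_hi):
            for tt in t_index.tile_range(t_lo, t_hi):
                pairs.add((qt, tt))
    out: list[Anchor] = []
    for qt, tt in sorted(pairs):
        q_table = q_index.tiles[qt]
        t_table = t_index.tiles[tt]
        small, big, flip = (q_table, t_table, False) if len(q_table) <= len(t_table) else (t_table, q_table, True)
        for code, hits in small.items():
            other = big.get(code)
            if not other:
                continue
            q_hits, t_hits = (hits, other) if not flip else (other, hits)
            for x, qf in q_hits:
                for y, tf in t_hits:
                    if qf == tf:  # forward-orientation match
                        out.append(Anchor(x=x, y=y, k=k, strand="+", kmer=code))
    out = sorted(set(out), key=lambda a: (a.x, a.y))
    return out


def merge_diagonal_anchors(anchors: Sequence[Anchor]) -> list[Fragment]:
    """Collapse same-diagonal runs of Cartesian-adjacent anchors.

    Anchors consecutive in (x, y) sorted order that share a forward
    diagonal merge into one fragment spanning first start to last end;
    the fragment weight is that merged length.
    """
    ordered = sorted(anchors, key=lambda a: (a.x, a.y))
    out: list[Fragment] = []
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and ordered[j + 1].f == ordered[i].f:
            j += 1
        first, last = ordered[i], ordered[j]
        length = last.x + last.k - first.x
        out.append(
            Fragment(
                xs=first.x,
                ys=first.y,
                xe=last.x + last.k,
                ye=last.y + last.k,
                weight=float(length),
            )
        )
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# Banded alignment with a single free gap
# ---------------------------------------------------------------------------


def _banded_align(q: str, t: str, params: BandedAlignParams) -> tuple[float, list[tuple[int, str]]]:
    """Plain banded global alignment (band around the main diagonal)."""
    lq, lt = len(q), len(t)
    B = max(params.band, abs(lt - lq) + 1)
    S = {(0, 0): 0.0}
    back: dict[tuple[int, int], str] = {}
    for i in range(lq + 1):
        j_lo = max(0, i - B)
        j_hi = min(lt, i + B)
        for j in range(j_lo, j_hi + 1):
            if i == 0 and j == 0:
                continue
            best, op = NEG_INF, "?"
            if i > 0 and j > 0 and (i - 1, j - 1) in S:
                v = S[(i - 1, j - 1)] + params.score(q[i - 1], t[j - 1])
                if v > best:
                    best, op = v, "M"
            if j > 0 and (i, j - 1) in S:
                v = S[(i, j - 1)] - params.delta
                if v > best:
                    best, op = v, "D"
            if i > 0 and (i - 1, j) in S:
                v = S[(i - 1, j)] - params.delta
                if v > best:
                    best, op = v, "I"
            if best > NEG_INF:
                S[(i, j)] = best
                back[(i, j)] = op
    if (lq, lt) not in S:
        # band cannot connect the corners: fall back to a pure split
        return _split_align(q, t, params)
    ops: list[tuple[int, str]] = []
    i, j = lq, lt
    while (i, j) != (0, 0):
        op = back[(i, j)]
        ops.append((1, op))
        if op == "M":
            i, j = i - 1, j - 1
        elif op == "D":
            j -= 1
        else:
            i -= 1
    ops.reverse()
    return S[(lq, lt)], _coalesce(ops)


def _split_align(q: str, t: str, params: BandedAlignParams) -> tuple[float, list[tuple[int, str]]]:
    """Degenerate fallback: one free gap, no banded edits around it."""
    lq, lt = len(q), len(t)
    if lq <= lt:
        # choose the split of q maximising ungapped matches at both ends
        best, bi = NEG_INF, 0
        for i in range(lq + 1):
            sc = sum(params.score(q[x], t[x]) for x in range(i))
            sc += sum(params.score(q[i + x], t[lt - (lq - i) + x]) for x in range(lq - i))
            if sc > best:
                best, bi = sc, i
        return best, _coalesce([(bi, "M"), (lt - lq, "D"), (lq - bi, "M")])
    score, ops = _split_align(t, q, params)
    return score, [(n, "I" if op == "D" else ("D" if op == "I" else op)) for n, op in ops]


def banded_one_gap_align(
    q_local: str,
    t_local: str,
    params: BandedAlignParams | None = None,
) -> tuple[float, list[tuple[int, str]]]:
    """Global alignment with banded edits plus at most one free gap.

    Two banded score matrices are used: the lower band follows the main
    diagonal from the start, the upper band follows the end diagonal
    (offset ``l_t - l_q``), and a path may take a single penalty-free
    horizontal jump from the lower to the upper matrix — the free gap.
    When the length difference fits inside the band a single banded
    matrix suffices.  Returns (score, CIGAR operations); operations are
    with respect to ``q_local`` (I consumes query, D consumes target).
    """
    if params is None:
        params = BandedAlignParams()
    if not q_local and not t_local:
        return 0.0, []
    if not q_local:
        return 0.0, [(len(t_local), "D")]
    if not t_local:
        return 0.0, [(len(q_local), "I")]
    if len(q_local) > len(t_local):
        score, ops = banded_one_gap_align(t_local, q_local, params)
        return score, [(n, "I" if op == "D" else ("D" if op == "I" else op)) for n, op in ops]
    lq, lt = len(q_local), len(t_local)
    G = lt - lq
    B = params.band
    q, t = q_local, t_local
    # lower matrix: |i - j| <= B; upper matrix: |j - i - G| <= B
    S0: dict[tuple[int, int], float] = {(0, 0): 0.0}
    back0: dict[tuple[int, int], str] = {}
    S1: dict[tuple[int, int], float] = {}
    back1: dict[tuple[int, int], tuple[str, int]] = {}  # op, jump source j0
    for i in range(lq + 1):
        for j in range(max(0, i - B), min(lt, i + B) + 1):
            if (i, j) == (0, 0):
                continue
            best, op = NEG_INF, "?"
            if i > 0 and j > 0 and (i - 1, j - 1) in S0:
                v = S0[(i - 1, j - 1)] + params.score(q[i - 1], t[j - 1])
                if v > best:
                    best, op = v, "M"
            if j > 0 and (i, j - 1) in S0:
                v = S0[(i, j - 1)] - params.delta
                if v > best:
                    best, op = v, "D"
            if i > 0 and (i - 1, j) in S0:
                v = S0[(i - 1, j)] - params.delta
                if v > best:
                    best, op = v, "I"
            if best > NEG_INF:
                S0[(i, j)] = best
                back0[(i, j)] = op
        # best lower-band cell of this row, for the free jump
        row_best, row_j = NEG_INF, -1
        for j in range(max(0, i - B), min(lt, i + B) + 1):
            if (i, j) in S0 and S0[(i, j)] > row_best:
                row_best, row_j = S0[(i, j)], j  # smallest j on ties: > keeps first
        for j in range(max(0, i + G - B), min(lt, i + G + B) + 1):
            best, op_src = NEG_INF, ("?", -1)
            if i > 0 and j > 0 and (i - 1, j - 1) in S1:
                v = S1[(i - 1, j - 1)] + params.score(q[i - 1], t[j - 1])
                if v > best:
                    best, op_src = v, ("M", -1)
            if j > 0 and (i, j - 1) in S1:
                v = S1[(i, j - 1)] - params.delta
                if v > best:
                    best, op_src = v, ("D", -1)
            if i > 0 and (i - 1, j) in S1:
                v = S1[(i - 1, j)] - params.delta
                if v > best:
                    best, op_src = v, ("I", -1)
            if row_j >= 0 and row_j < j:
                v = row_best  # free horizontal jump from (i, row_j) to (i, j)
                if v > best:
                    best, op_src = v, ("J", row_j)
            if best > NEG_INF:
                S1[(i, j)] = best
                back1[(i, j)] = op_src
    no_gap = S0.get((lq, lt), NEG_INF)  # reachable when the bands overlap
    one_gap = S1.get((lq, lt), NEG_INF)
    if no_gap == NEG_INF and one_gap == NEG_INF:
        return _split_align(q, t, params)
    ops: list[tuple[int, str]] = []
    i, j = lq, lt
    layer = 1 if one_gap >= no_gap else 0
    while (i, j) != (0, 0):
        if layer == 1:
            op, src = back1[(i, j)]
            if op == "J":
                ops.append((j - src, "D"))
                j = src
                layer = 0
                continue
        else:
            op = back0[(i, j)]
        ops.append((1, op))
        if op == "M":
            i, j = i - 1, j - 1
        elif op == "D":
            j -= 1
        else:
            i -= 1
    ops.reverse()
    return max(no_gap, one_gap), _coalesce(ops)


# ---------------------------------------------------------------------------
# Stitching a refined chain into an alignment record
# ---------------------------------------------------------------------------


def stitch_alignment(
    query: str,
    target: str,
    fragments: Sequence[Fragment],
    chain: ChainResult,
    params: BandedAlignParams | None = None,
    qname: str = "query",
    tname: str = "target",
    strand: str = "+",
) -> AlignmentRecord:
    """Fill the gaps between chained fragments and emit one record.

    Chained fragments become M runs (scored base by base); inter-fragment
    regions are aligned with :func:`banded_one_gap_align`.  Query bases
    outside the chained span are soft-clipped.  Regions longer than
    ``max_junction`` are reported as plain I+D junctions without
    base-level alignment.
    """
    if params is None:
        params = BandedAlignParams()
    if not chain.fragments:
        raise ValueError("cannot stitch an empty chain")
    members = [fragments[i] for i in chain.fragments]
    for a, b in zip(members, members[1:]):
        if b.xs < a.xe or b.ys < a.ye:
            raise ValueError("chain fragments are not colinear; upstream bug")
    ops: list[tuple[int, str]] = []
    score = 0.0
    first, last = members[0], members[-1]
    if first.xs > 0:
        ops.append((int(first.xs), "S"))
    prev = None
    for fr in members:
        if prev is not None:
            q_gap = query[int(prev.xe) : int(fr.xs)]
            t_gap = target[int(prev.ye) : int(fr.ys)]
            if max(len(q_gap), len(t_gap)) > params.max_junction:
                ops.extend([(len(q_gap), "I"), (len(t_gap), "D")])
            else:
                gscore, gops = banded_one_gap_align(q_gap, t_gap, params)
                score += gscore
                ops.extend(gops)
        span_q = int(fr.xe - fr.xs)
        span_t = int(fr.ye - fr.ys)
        if span_q == span_t:
            ops.append((span_q, "M"))
            score += sum(
                params.score(query[int(fr.xs) + o], target[int(fr.ys) + o]) for o in range(span_q)
            )
        else:  # super-fragment whose corners are off-diagonal
            gscore, gops = banded_one_gap_align(
                query[int(fr.xs) : int(fr.xe)], target[int(fr.ys) : int(fr.ye)], params
            )
            score += gscore
            ops.extend(gops)
        prev = fr
    if int(last.xe) < len(query):
        ops.append((len(query) - int(last.xe), "S"))
    return AlignmentRecord(
        qname=qname,
        tname=tname,
        pos=int(first.ys),
        strand=strand,
        cigar=_coalesce(ops),
        score=score,
        query_length=len(query),
    )
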