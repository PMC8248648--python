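"""Minimizer indexing with adaptive density, and anchor matching.

A minimizer index samples, for every window of ``w`` consecutive k-mers,
the position of the lexicographically least *canonical* k-mer (the
smaller of the k-mer and its reverse complement).  The global index adds
three density controls on top of the standard scheme:

* ``f_max``  - k-mers whose genome-wide multiplicity exceeds this are
  removed entirely;
* ``w_genome`` - the target is partitioned into intervals of this length;
* ``n_max``  - within each interval, surviving minimizers are retained in
  increasing order of genome-wide multiplicity until ``n_max`` are kept
  (ties broken by position), thinning unique regions while keeping the
  rarest (most discriminative) seeds in repeats.

A second, *local* index at finer resolution (``k_l < k``, ``w_l < w``)
is a collection of independent minimizer tables for substrings of length
``w_local`` tiling a sequence; it supplies dense anchors when a coarse
chain is refined.

Coordinates are 0-based half-open throughout.  k-mers containing ``N``
are never indexed or matched.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GlobalIndexParams",
    "LocalIndexParams",
    "Anchor",
    "GlobalIndex",
    "LocalIndex",
    "compute_minimizers",
    "build_global_index",
    "match_anchors",
    "build_local_index",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class GlobalIndexParams:
    """Parameters of the adaptive global minimizer index."""

    k: int = 15
    w: int = 10
    f_max: int = 50
    n_max: int = 10
    w_genome: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1 or self.w < 1 or self.f_max < 1 or self.n_max < 1:
            raise ValueError("k, w, f_max and n_max must all be >= 1")
        if self.w_genome < self.w + self.k:
            raise ValueError("w_genome must be at least w + k")


@dataclass(frozen=True)
class LocalIndexParams:
    """Parameters of the tiled local minimizer index (finer than global)."""

    k: int = 7
    w: int = 5
    w_local: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1 or self.w < 1:
            raise ValueError("k and w must be >= 1")
        if self.w_local < self.w + self.k:
            raise ValueError("w_local must be at least w + k")

    def check_against(self, global_params: GlobalIndexParams) -> None:
        if not (self.k < global_params.k and self.w < global_params.w):
            raise ValueError("local k and w must be smaller than the global ones")


@dataclass(frozen=True)
class Anchor:
    """An exact k-length match: query offset x, target offset y.

    ``strand`` is "+" when the query k-mer equals the target k-mer and
    "-" when it equals its reverse complement.  The forward diagonal
    ``f = y - x`` is constant along gap-free forward matches, the
    reverse diagonal ``r = x + y`` along gap-free reverse matches.
    """

    x: int
    y: int
    k: int
    strand: str = "+"
    kmer: int = -1  # canonical k-mer code; -1 when unknown
    tid: str = ""

    @property
    def f(self) -> int:
        return self.y - self.x

    @property
    def r(self) -> int:
        return self.x + self.y


def _canonical_minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, bool]]:
    """All (position, canonical code, is_forward_canonical) minimizers.

    ``is_forward_canonical`` records whether the forward-strand k-mer at
    the position equals the canonical k-mer (ties, i.e. palindromes,
    count as forward).  Standard scheme: for every window of ``w``
    consecutive valid k-mers, report the leftmost occurrence of the
    least canonical k-mer; duplicate reports are collapsed.  Windows
    containing invalid (N-bearing) k-mers consider only the valid ones.
    """
    n = len(seq)
    if n < k:
        return []
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = 0
    rev = 0
    valid = 0  # number of consecutive valid bases ending here
    codes: list[tuple[int, bool] | None] = [None] * (n - k + 1)
    for i, ch in enumerate(seq):
        c = _CODE.get(ch)
        if c is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rev = (rev >> 2) | ((3 - c) << shift)
        valid += 1
        if valid >= k:
            pos = i - k + 1
            if fwd <= rev:
                codes[pos] = (fwd, True)
            else:
                codes[pos] = (rev, False)
    out: list[tuple[int, int, bool]] = []
    last_pos = -1
    total = n - k + 1
    for wstart in range(0, max(1, total - w + 1)):
        wend = min(total, wstart + w)
        best = None
        best_pos = -1
        for pos in range(wstart, wend):
            entry = codes[pos]
            if entry is None:
                continue
            if best is None or entry[0] < best[0]:
                best = entry
                best_pos = pos
        if best is not None and best_pos != last_pos:
            out.append((best_pos, best[0], best[1]))
            last_pos = best_pos
    # collapse duplicates while preserving order, then sort by position
    seen: set[int] = set()
    uniq = []
    for pos, code, isfwd in sorted(out):
        if pos not in seen:
            seen.add(pos)
            uniq.append((pos, code, isfwd))
    return uniq


def compute_minimizers(seq: str, k: int, w: int) -> list[tuple[int, str]]:
    """Minimizers of ``seq``: (position, canonical k-mer) in position order.

    For every window of ``w`` consecutive k-mers the leftmost occurrence
    of the lexicographically least canonical k-mer is reported; k-mers
    containing N never qualify.  A sequence shorter than ``k`` yields an
    empty list.
    """
    return [(pos, _decode(code, k)) for pos, code, _ in _canonical_minimizers(seq, k, w)]


@dataclass
class GlobalIndex:
    """Adaptive global minimizer index over one or more target sequences."""

    params: GlobalIndexParams
    # canonical code -> list of (tid, position, forward_canonical)
    entries: dict[int, list[tuple[str, int, bool]]] = field(default_factory=dict)
    target_lengths: dict[str, int] = field(default_factory=dict)

    def lookup(self, code: int) -> list[tuple[str, int, bool]]:
        return self.entries.get(code, [])

    # -- serialization (JSON-lines sidecar) --------------------------------

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"format": "cgmap-index", "version": 1,
                                 "params": vars(self.params),
                                 "target_lengths": self.target_lengths}) + "\n")
            for code, hits in sorted(self.entries.items()):
                fh.write(json.dumps([code, [[t, p, int(f)] for t, p, f in hits]]) + "\n")

    @classmethod
    def load(cls, path: str) -> "GlobalIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "cgmap-index":
                raise ValueError("not a cgmap index file")
            idx = cls(GlobalIndexParams(**header["params"]),
                      target_lengths=header["target_lengths"])
            for line in fh:
                code, hits = json.loads(line)
                idx.entries[int(code)] = [(t, p, bool(f)) for t, p, f in hits]
        return idx


def build_global_index(
    targets: dict[str, str] | Iterable[tuple[str, str]],
    params: GlobalIndexParams | None = None,
) -> GlobalIndex:
    """Three-stage construction of the adaptive global index.

    (1) standard (k, w) minimizers per target; (2) k-mers of genome-wide
    multiplicity above ``f_max`` removed; (3) per ``w_genome`` interval,
    minimizers kept in increasing multiplicity (ties by position) until
    ``n_max`` are retained.
    """
    if params is None:
        params = GlobalIndexParams()
    items = list(targets.items()) if isinstance(targets, dict) else list(targets)
    if not any(seq for _, seq in items):
        raise ValueError("all target sequences are empty; nothing to index")
    # stage 1
    per_target: dict[str, list[tuple[int, int, bool]]] = {}
    mult: dict[int, int] = {}
    for tid, seq in items:
        mins = _canonical_minimizers(seq, params.k, params.w)
        per_target[tid] = mins
        for _, code, _ in mins:
            mult[code] = mult.get(code, 0) + 1
    idx = GlobalIndex(params, target_lengths={tid: len(seq) for tid, seq in items})
    for tid, mins in per_target.items():
        # stage 2: frequency filter
        survivors = [(pos, code, isfwd) for pos, code, isfwd in mins if mult[code] <= params.f_max]
        # stage 3: per-interval thinning by multiplicity
        by_interval: dict[int, list[tuple[int, int, bool]]] = {}
        for pos, code, isfwd in survivors:
            by_interval.setdefault(pos // params.w_genome, []).append((pos, code, isfwd))
        for interval in sorted(by_interval):
            ranked = sorted(by_interval[interval], key=lambda e: (mult[e[1]], e[0]))
            for pos, code, isfwd in sorted(ranked[: params.n_max]):
                idx.entries.setdefault(code, []).append((tid, pos, isfwd))
    for hits in idx.entries.values():
        hits.sort()
    return idx


def match_anchors(query: str, index: GlobalIndex) -> list[Anchor]:
    """Anchors between ``query`` and the indexed targets, sorted by (x, y).

    Query minimizers are computed with the index's (k, w) and looked up
    by canonical k-mer; each hit yields one anchor whose strand is
    forward when query and target k-mers agree on orientation.
    """
    if not query:
        raise ValueError("query must be non-empty")
    p = index.params
    anchors: list[Anchor] = []
    for x, code, q_fwd in _canonical_minimizers(query, p.k, p.w):
        for tid, y, t_fwd in index.lookup(code):
            strand = "+" if q_fwd == t_fwd else "-"
            anchors.append(Anchor(x=x, y=y, k=p.k, strand=strand, kmer=code, tid=tid))
    anchors.sort(key=lambda a: (a.tid, a.x, a.y))
    return anchors


@dataclass
class LocalIndex:
    """Per-tile minimizer tables with absolute positions."""

    params: LocalIndexParams
    length: int
    # one dict per tile: canonical code -> [(absolute position, forward_canonical)]
    tiles: list[dict[int, list[tuple[int, bool]]]] = field(default_factory=list)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def tile_range(self, lo: int, hi: int) -> range:
        """Indexes of tiles overlapping the half-open interval [lo, hi)."""
        w = self.params.w_local
        first = max(0, lo // w)
        last = min(self.n_tiles, (max(lo, hi - 1)) // w + 1)
        return range(first, last)


def build_local_index(seq: str, params: LocalIndexParams | None = None) -> LocalIndex:
    """One minimizer table per ``w_local`` tile; ceil(len/w_local) tiles."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    if params is None:
        params = LocalIndexParams()
    w = params.w_local
    n_tiles = (len(seq) + w - 1) // w
    idx = LocalIndex(params, len(seq))
    for t in range(n_tiles):
        offset = t * w
        table: dict[int, list[tuple[int, bool]]] = {}
        for pos, code, isfwd in _canonical_minimizers(seq[offset : offset + w], params.k, params.w):
            table.setdefault(code, []).append((offset + pos, isfwd))
        idx.tiles.append(table)
    return idx
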