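"""Anchor clustering: rough diagonal bands, fine non-overlapping clusters,
and boundary splitting.

Rough clustering greedily partitions anchors, sorted by diagonal and
then query position, at diagonal gaps larger than ``d_rough``; short
intervals are noise and are dropped.  On high-accuracy data each rough
cluster is refined into *fine* clusters — runs of anchors whose k-mer is
unique within the cluster, merged across tandem-repeat blocks when their
facing corners are close in diagonal (< ``d_fine``) and in the plane
(<= ``g_dist``), absorbing the repeat's non-unique anchors inside the
trapezoid between them.  Overlapping fine clusters are finally split at
each other's boundaries so that chaining them as super-fragments cannot
skip variation hidden inside a repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .index import Anchor

__all__ = [
    "ClusterParams",
    "RoughCluster",
    "FineCluster",
    "rough_cluster",
    "fine_cluster",
    "split_clusters",
]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for rough and fine clustering (all in bases)."""

    d_rough: int = 200
    min_cluster_size: int = 3
    d_fine: int = 500
    g_dist: int = 5000

    def __post_init__(self) -> None:
        if min(self.d_rough, self.min_cluster_size, self.d_fine, self.g_dist) <= 0:
            raise ValueError("all clustering thresholds must be positive")


@dataclass
class RoughCluster:
    anchors: list[Anchor]
    strand: str

    @property
    def x_span(self) -> tuple[int, int]:
        return (min(a.x for a in self.anchors), max(a.x + a.k for a in self.anchors))

    @property
    def y_span(self) -> tuple[int, int]:
        return (min(a.y for a in self.anchors), max(a.y + a.k for a in self.anchors))


@dataclass
class FineCluster:
    anchors: list[Anchor]
    strand: str
    xs: int = 0
    ys: int = 0
    xe: int = 0
    ye: int = 0

    def recompute_corners(self) -> None:
        self.xs = min(a.x for a in self.anchors)
        self.ys = min(a.y for a in self.anchors)
        self.xe = max(a.x + a.k for a in self.anchors)
        self.ye = max(a.y + a.k for a in self.anchors)


def _diag(anchor: Anchor, strand: str) -> int:
    return anchor.f if strand == "+" else anchor.r


def rough_cluster(anchors: Sequence[Anchor], params: ClusterParams) -> list[RoughCluster]:
    """Greedy diagonal-band partition of anchors, per strand.

    Forward anchors are ordered by (forward diagonal, x) and split at
    diagonal gaps > ``d_rough``; reverse anchors likewise on the reverse
    diagonal.  Intervals smaller than ``min_cluster_size`` are dropped.
    """
    clusters: list[RoughCluster] = []
    for strand in ("+", "-"):
        sub = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (_diag(a, strand), a.x),
        )
        if not sub:
            continue
        run = [sub[0]]
        for a in sub[1:]:
            if _diag(a, strand) - _diag(run[-1], strand) > params.d_rough:
                if len(run) >= params.min_cluster_size:
                    clusters.append(RoughCluster(run, strand))
                run = [a]
            else:
                run.append(a)
        if len(run) >= params.min_cluster_size:
            clusters.append(RoughCluster(run, strand))
    return clusters


def _in_trapezoid(a: Anchor, left: FineCluster, right: FineCluster, d_fine: int, strand: str) -> bool:
    """Is the anchor inside the band between the facing cluster corners?

    The region is bounded by x in [left.xe, right.xs] and, vertically, by
    the line joining the facing corners shifted by +-d_fine.
    """
    if not (left.xe <= a.x <= right.xs):
        return False
    if right.xs == left.xe:
        mid = (left.ye + right.ys) / 2.0
    else:
        t = (a.x - left.xe) / (right.xs - left.xe)
        mid = left.ye + t * (right.ys - left.ye)
    return mid - d_fine <= a.y <= mid + d_fine


def fine_cluster(rough: RoughCluster, params: ClusterParams) -> list[FineCluster]:
    """Refine one rough cluster into non-overlapping fine clusters.

    Unique anchors (k-mer occurring once in the cluster) seed runs;
    runs are merged when their facing corners differ by < ``d_fine`` in
    diagonal and <= ``g_dist`` in the plane; non-unique anchors between
    merged runs are absorbed when they fall in the connecting trapezoid;
    remaining non-unique anchors are discarded.
    """
    strand = rough.strand
    anchors = sorted(rough.anchors, key=lambda a: (a.x, a.y))
    counts: dict[int, int] = {}
    for a in anchors:
        counts[a.kmer] = counts.get(a.kmer, 0) + 1
    unique = [counts[a.kmer] == 1 for a in anchors]

    # (1) initialize fine clusters as runs of unique anchors
    runs: list[FineCluster] = []
    cur: list[Anchor] = []
    for a, u in zip(anchors, unique):
        if not u:
            if cur:
                runs.append(FineCluster(cur, strand))
                cur = []
            continue
        if cur:
            prev = cur[-1]
            ddiag = abs(_diag(a, strand) - _diag(prev, strand))
            dist = math.hypot(a.x - (prev.x + prev.k), a.y - (prev.y + prev.k))
            if ddiag >= params.d_fine or dist > params.g_dist:
                runs.append(FineCluster(cur, strand))
                cur = []
        cur.append(a)
    if cur:
        runs.append(FineCluster(cur, strand))
    if not runs:
        return []
    for r in runs:
        r.recompute_corners()
    runs.sort(key=lambda c: (c.xs, c.ys))

    # (2) merge clusters whose facing corners are close; union-find groups
    parent = list(range(len(runs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def corner_diag(x: int, y: int) -> int:
        return (y - x) if strand == "+" else (x + y)

    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            a, b = runs[i], runs[j]
            ddiag = abs(corner_diag(a.xe, a.ye) - corner_diag(b.xs, b.ys))
            dist = math.hypot(b.xs - a.xe, b.ys - a.ye)
            if ddiag < params.d_fine and dist <= params.g_dist:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[max(pi, pj)] = min(pi, pj)

    groups: dict[int, list[int]] = {}
    for i in range(len(runs)):
        groups.setdefault(find(i), []).append(i)

    out: list[FineCluster] = []
    nonunique = [a for a, u in zip(anchors, unique) if not u]
    for members in groups.values():
        members.sort(key=lambda i: runs[i].xs)
        merged_anchors: list[Anchor] = []
        for idx0 in members:
            merged_anchors.extend(runs[idx0].anchors)
        # (3) absorb non-unique anchors in the trapezoids between
        # consecutive merged members
        for a_idx, b_idx in zip(members, members[1:]):
            left, right = runs[a_idx], runs[b_idx]
            for a in nonunique:
                if _in_trapezoid(a, left, right, params.d_fine, strand):
                    merged_anchors.append(a)
        merged_anchors = sorted(set(merged_anchors), key=lambda a: (a.x, a.y))
        fc = FineCluster(merged_anchors, strand)
        fc.recompute_corners()
        out.append(fc)
    out.sort(key=lambda c: (c.xs, c.ys))
    return out


def split_clusters(fine: Sequence[FineCluster]) -> list[FineCluster]:
    """Split fine clusters at the boundaries of overlapping neighbours.

    Every cluster's query-axis and target-axis span is cut at the start
    and end coordinates of *other* clusters falling strictly inside it;
    the pieces' corners are recomputed from the first/last anchors on
    each side, so anchors are never duplicated.  Empty pieces vanish.
    """
    out: list[FineCluster] = []
    for ci, c in enumerate(fine):
        x_cuts = sorted(
            {
                v
                for cj, other in enumerate(fine)
                if cj != ci
                for v in (other.xs, other.xe)
                if c.xs < v < c.xe
            }
        )
        y_cuts = sorted(
            {
                v
                for cj, other in enumerate(fine)
                if cj != ci
                for v in (other.ys, other.ye)
                if c.ys < v < c.ye
            }
        )
        if not x_cuts and not y_cuts:
            out.append(c)
            continue
        # bin anchors by the grid induced by the cuts
        pieces: dict[tuple[int, int], list[Anchor]] = {}
        for a in c.anchors:
            xi = sum(1 for v in x_cuts if a.x >= v)
            yi = sum(1 for v in y_cuts if a.y >= v)
            pieces.setdefault((xi, yi), []).append(a)
        for key in sorted(pieces):
            fc = FineCluster(sorted(pieces[key], key=lambda a: (a.x, a.y)), c.strand)
            fc.recompute_corners()
            out.append(fc)
    out.sort(key=lambda c: (c.xs, c.ys))
    return out
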