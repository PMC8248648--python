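"""End-to-end toy aligner: FASTA in, SAM/PAF out.

Per read: minimizer anchors against the adaptive global index; rough
clustering per strand; either direct anchor fragments (low-accuracy
presets) or fine-cluster super-fragments (high-accuracy presets);
inversion-aware concave-gap chaining across candidate loci; per
same-strand chain segment, local-minimizer re-anchoring, diagonal
merging, a second chaining pass and banded one-free-gap stitching; and
finally mapping-quality assignment from the best/second-best locus
margin.  Output is deterministic given inputs and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .chain import ChainResult, Fragment, GapFunction, chain_fragments
from .cluster import ClusterParams, FineCluster, fine_cluster, rough_cluster, split_clusters
from .index import (
    Anchor,
    GlobalIndex,
    GlobalIndexParams,
    LocalIndex,
    LocalIndexParams,
    build_global_index,
    build_local_index,
    match_anchors,
    revcomp,
)
from .invchain import InversionChainConfig, chain_with_inversions
from .refine import (
    AlignmentRecord,
    BandedAlignParams,
    banded_one_gap_align,
    local_anchors,
    merge_diagonal_anchors,
    stitch_alignment,
)

__all__ = [
    "PresetConfig",
    "PRESETS",
    "AlignmentRecord",
    "align",
    "align_read",
    "assign_mapq",
    "evaluate_mapping",
    "sam_header",
    "to_sam",
    "to_paf",
    "read_fasta",
]


@dataclass(frozen=True)
class PresetConfig:
    """Technology preset bundling all stage parameters."""

    name: str
    index_params: GlobalIndexParams = GlobalIndexParams()
    local_params: LocalIndexParams = LocalIndexParams()
    cluster_params: ClusterParams = ClusterParams()
    gap_a: float = 0.25
    gap_b: float = 1.0
    inversion_open: float = 0.0
    align_params: BandedAlignParams = BandedAlignParams()
    fine_path: bool = False  # fine clustering + super-fragments vs direct anchors
    locus_gap: int = 0  # 0: use the read length; else a fixed base distance

    def gap_fwd(self) -> GapFunction:
        return GapFunction.log_cost(self.gap_a, self.gap_b)

    def inversion_config(self) -> InversionChainConfig:
        return InversionChainConfig(
            gap_fwd=self.gap_fwd(),
            gap_rev=GapFunction.log_cost(self.gap_a, self.gap_b),
            inversion_open=self.inversion_open,
        )


# Presets index more densely than the library defaults: on toy genomes
# every k-mer is unique, so the per-interval thinning tie-break (position)
# keeps a prefix clump of each interval; a smaller interval with a
# proportional budget spreads the retained seeds evenly enough to anchor
# kilobase reads anywhere.
_PRESET_INDEX = GlobalIndexParams(k=15, w=10, f_max=50, n_max=15, w_genome=250)

PRESETS: dict[str, PresetConfig] = {
    "CLR": PresetConfig(
        name="CLR",
        index_params=_PRESET_INDEX,
        cluster_params=ClusterParams(d_rough=200, min_cluster_size=3, d_fine=500),
        fine_path=False,
    ),
    "ONT": PresetConfig(
        name="ONT",
        index_params=_PRESET_INDEX,
        cluster_params=ClusterParams(d_rough=200, min_cluster_size=3, d_fine=500),
        fine_path=False,
    ),
    "HiFi": PresetConfig(
        name="HiFi",
        index_params=_PRESET_INDEX,
        cluster_params=ClusterParams(d_rough=150, min_cluster_size=10, d_fine=500),
        fine_path=True,
    ),
    "CONTIG": PresetConfig(
        name="CONTIG",
        index_params=_PRESET_INDEX,
        cluster_params=ClusterParams(d_rough=150, min_cluster_size=10, d_fine=500),
        fine_path=True,
    ),
}


def read_fasta(path: str) -> dict[str, str]:
    """Multi-record FASTA/FASTQ reader (format sniffed from the content)."""
    from Bio import SeqIO

    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, fmt)}


# ---------------------------------------------------------------------------
# Candidate loci and fragments
# ---------------------------------------------------------------------------


def _group_loci(clusters: list, locus_gap: int) -> list[list]:
    """Group rough clusters into candidate loci by target proximity."""
    ordered = sorted(clusters, key=lambda c: c.y_span[0])
    loci: list[list] = []
    for c in ordered:
        if loci and c.y_span[0] - max(m.y_span[1] for m in loci[-1]) <= locus_gap:
            loci[-1].append(c)
        else:
            loci.append([c])
    return loci


def _fragments_direct(clusters: list) -> tuple[list[Fragment], list[list[Anchor]]]:
    frags: list[Fragment] = []
    members: list[list[Anchor]] = []
    for c in clusters:
        for a in c.anchors:
            frags.append(
                Fragment(xs=a.x, ys=a.y, xe=a.x + a.k, ye=a.y + a.k, weight=float(a.k), strand=a.strand)
            )
            members.append([a])
    return frags, members


def _fragments_fine(clusters: list, params: ClusterParams) -> tuple[list[Fragment], list[list[Anchor]]]:
    fine: list[FineCluster] = []
    for c in clusters:
        fine.extend(fine_cluster(c, params))
    fine = split_clusters(fine)
    frags: list[Fragment] = []
    members: list[list[Anchor]] = []
    for fc in fine:
        weight = float(sum(a.k for a in fc.anchors))
        frags.append(
            Fragment(xs=fc.xs, ys=fc.ys, xe=fc.xe, ye=fc.ye, weight=weight, strand=fc.strand)
        )
        members.append(fc.anchors)
    return frags, members


# ---------------------------------------------------------------------------
# Per-segment refinement
# ---------------------------------------------------------------------------


def _refine_segment(
    query: str,
    target: str,
    tid: str,
    qname: str,
    strand: str,
    q_lo: int,
    q_hi: int,
    t_lo: int,
    t_hi: int,
    seg_anchors: list[Anchor],
    config: PresetConfig,
) -> AlignmentRecord | None:
    """Local re-anchoring + second chaining pass + stitching of one segment.

    The segment is normalised to forward orientation: for a reverse
    segment the query subinterval is reverse complemented.  Record
    coordinates are mapped back to the full read and target afterwards.
    """
    qseg = query[q_lo:q_hi] if strand == "+" else revcomp(query[q_lo:q_hi])
    tseg = target[t_lo:t_hi]
    if not qseg or not tseg:
        return None
    lp = config.local_params
    q_index = build_local_index(qseg, lp)
    t_index = build_local_index(tseg, lp)
    # chained anchors mapped into segment-local, forward coordinates
    local_chain: list[Anchor] = []
    for a in seg_anchors:
        if strand == "+":
            local_chain.append(Anchor(x=a.x - q_lo, y=a.y - t_lo, k=a.k, strand="+", kmer=a.kmer))
        else:
            local_chain.append(
                Anchor(x=q_hi - (a.x + a.k), y=a.y - t_lo, k=a.k, strand="+", kmer=a.kmer)
            )
    anchors = local_anchors(qseg, tseg, local_chain, q_index, t_index)
    if not anchors:
        # fall back to the coarse anchors themselves
        anchors = local_chain
    frags = merge_diagonal_anchors(anchors)
    if not frags:
        return None
    chain = chain_fragments(frags, config.gap_fwd())
    if not chain.fragments:
        return None
    rec = stitch_alignment(
        qseg,
        tseg,
        frags,
        chain,
        params=config.align_params,
        qname=qname,
        tname=tid,
        strand=strand,
    )
    _extend_ends(rec, qseg, tseg, config.align_params)
    rec.pos += t_lo
    # extend soft clips to the full read, in the record's (oriented) frame
    lead = q_lo if strand == "+" else len(query) - q_hi
    trail = len(query) - q_hi if strand == "+" else q_lo
    cigar = list(rec.cigar)
    if cigar and cigar[0][1] == "S":
        cigar[0] = (cigar[0][0] + lead, "S")
    elif lead:
        cigar.insert(0, (lead, "S"))
    if cigar and cigar[-1][1] == "S":
        cigar[-1] = (cigar[-1][0] + trail, "S")
    elif trail:
        cigar.append((trail, "S"))
    rec.cigar = cigar
    rec.query_length = len(query)
    rec.seq = query if strand == "+" else revcomp(query)
    return rec


# ---------------------------------------------------------------------------
# The aligner
# ---------------------------------------------------------------------------


def _extend_ends(rec: AlignmentRecord, qseg: str, tseg: str, params: BandedAlignParams,
                 cap: int = 400) -> None:
    """Turn terminal soft-clips into aligned bases when profitable.

    The clipped piece is aligned globally against the equal-length target
    window adjacent to the record; the extension is kept only when it
    scores positively, so garbage tails stay clipped.
    """
    cigar = list(rec.cigar)
    if cigar and cigar[0][1] == "S" and 0 < cigar[0][0] <= cap:
        lead = cigar[0][0]
        take = min(lead, rec.pos)
        if take > 0:
            qpiece = qseg[lead - take : lead]
            tpiece = tseg[rec.pos - take : rec.pos]
            score, ops = banded_one_gap_align(qpiece, tpiece, params)
            if score > 0:
                rest = [(lead - take, "S")] if lead > take else []
                cigar = rest + ops + cigar[1:]
                rec.pos -= take
                rec.score += score
    if cigar and cigar[-1][1] == "S" and 0 < cigar[-1][0] <= cap:
        trail = cigar[-1][0]
        t_end = rec.pos + sum(n for n, op in cigar[:-1] if op in "MD")
        take = min(trail, len(tseg) - t_end)
        if take > 0:
            qpiece = qseg[len(qseg) - trail : len(qseg) - trail + take]
            tpiece = tseg[t_end : t_end + take]
            score, ops = banded_one_gap_align(qpiece, tpiece, params)
            if score > 0:
                rest = [(trail - take, "S")] if trail > take else []
                cigar = cigar[:-1] + ops + rest
                rec.score += score
    out: list[tuple[int, str]] = []
    for n, op in cigar:
        if n and out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        elif n:
            out.append((n, op))
    rec.cigar = out


def align_read(
    qname: str,
    query: str,
    targets: dict[str, str],
    index: GlobalIndex,
    config: PresetConfig,
) -> list[AlignmentRecord]:
    """Align one read; returns primary + supplementary records (or unmapped)."""
    unmapped = AlignmentRecord(
        qname=qname, tname="*", pos=0, strand="+", cigar=[], score=0.0, mapq=0,
        query_length=len(query), seq=query,
    )
    try:
        anchors = match_anchors(query, index)
    except ValueError:
        return [unmapped]
    if not anchors:
        return [unmapped]
    by_tid: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_tid.setdefault(a.tid, []).append(a)

    candidates: list[tuple[float, str, ChainResult, list[Fragment], list[list[Anchor]]]] = []
    for tid, tanchors in by_tid.items():
        rough = rough_cluster(tanchors, config.cluster_params)
        locus_gap = config.locus_gap or max(len(query), 1000)
        for locus in _group_loci(rough, locus_gap):
            if config.fine_path:
                frags, members = _fragments_fine(locus, config.cluster_params)
            else:
                frags, members = _fragments_direct(locus)
            if not frags:
                continue
            chain = chain_with_inversions(frags, config.inversion_config())
            if chain.fragments:
                candidates.append((chain.score, tid, chain, frags, members))
    if not candidates:
        return [unmapped]
    candidates.sort(key=lambda c: -c[0])
    best = candidates[0]
    second = candidates[1][0] if len(candidates) > 1 else None
    mapq = assign_mapq(best[0], second)

    _, tid, chain, frags, members = best
    target = targets[tid]
    # maximal same-strand runs of the chained fragments
    segments: list[tuple[str, list[int]]] = []
    for ci, fi in enumerate(chain.fragments):
        st = frags[fi].strand
        if segments and segments[-1][0] == st:
            segments[-1][1].append(fi)
        else:
            segments.append((st, [fi]))
    records: list[AlignmentRecord] = []
    bounds = []
    for st, fids in segments:
        bounds.append(
            (
                int(min(frags[fi].xs for fi in fids)),
                int(max(frags[fi].xe for fi in fids)),
                int(min(frags[fi].ys for fi in fids)),
                int(max(frags[fi].ye for fi in fids)),
            )
        )
    for si, (st, fids) in enumerate(segments):
        seg_anchors = [a for fi in fids for a in members[_frag_index(frags, fi)]]
        q_lo, q_hi, t_lo, t_hi = bounds[si]
        # extend the outermost segments to the read ends, and interior
        # boundaries to the midpoint of the gap to the neighbouring
        # segment, so refinement covers the breakpoints between segments
        if si == 0:
            d_lo = q_lo
        else:
            d_lo = max(0, (q_lo - bounds[si - 1][1] + 1) // 2)
        if si == len(segments) - 1:
            d_hi = len(query) - q_hi
        else:
            d_hi = max(0, (bounds[si + 1][0] - q_hi) // 2)
        q_lo -= d_lo
        q_hi += d_hi
        if st == "+":
            t_lo -= d_lo
            t_hi += d_hi
        else:
            t_lo -= d_hi
            t_hi += d_lo
        margin = config.align_params.band * 2 + 50
        t_lo = max(0, t_lo - margin)
        t_hi = min(len(target), t_hi + margin)
        rec = _refine_segment(
            query, target, tid, qname, st, q_lo, q_hi, t_lo, t_hi, seg_anchors, config
        )
        if rec is not None:
            records.append(rec)
    if not records:
        return [unmapped]
    # primary = longest record on the read's majority orientation
    span_by_strand = {"+": 0, "-": 0}
    for rec in records:
        span_by_strand[rec.strand] += rec.query_span
    major = "+" if span_by_strand["+"] >= span_by_strand["-"] else "-"
    on_major = [i for i in range(len(records)) if records[i].strand == major]
    primary = max(on_major, key=lambda i: records[i].query_span)
    for i, rec in enumerate(records):
        rec.is_supplementary = i != primary
        rec.mapq = mapq
    return records


def _frag_index(frags: list[Fragment], fi: int) -> int:
    return fi  # fragments are indexed positionally; kept for readability


def align(
    reference: dict[str, str] | str,
    queries: dict[str, str] | str,
    config: PresetConfig | str = "ONT",
    index: GlobalIndex | None = None,
) -> Iterator[AlignmentRecord]:
    """Align all queries against the reference; yields records in input order."""
    if isinstance(config, str):
        config = PRESETS[config]
    targets = read_fasta(reference) if isinstance(reference, str) else reference
    reads = read_fasta(queries) if isinstance(queries, str) else queries
    if not reads:
        raise ValueError("no query sequences")
    if index is None:
        index = build_global_index(targets, config.index_params)
    for qname, seq in reads.items():
        yield from align_read(qname, seq, targets, index, config)


def assign_mapq(best: float, second: float | None) -> int:
    """Monotone mapping quality from the best/second-best score margin.

    A unique placement maps to 60; exactly tied placements to 0;
    otherwise ``40 * margin / best`` clamped to [0, 60].
    """
    if best <= 0:
        return 0
    if second is None:
        return 60
    margin = max(0.0, best - second)
    if margin == 0.0:
        return 0
    return int(max(0, min(60, round(40.0 * margin / best))))


# ---------------------------------------------------------------------------
# Mapping evaluation (overlap-fraction metric)
# ---------------------------------------------------------------------------


def evaluate_mapping(
    truth: dict[str, tuple[int, int]],
    records: Sequence[AlignmentRecord],
    fractions: Sequence[float] = (0.1, 0.4, 0.7),
    mapq_thresholds: Sequence[int] = (0, 20),
) -> dict[float, dict[int, float]]:
    """Accuracy of primary records at each overlap fraction and MAPQ cutoff.

    A record is correct when the overlap of its reported target interval
    with the truth interval is at least ``fraction`` of the truth length.
    Records whose query has no truth interval are excluded with a warning.
    """
    prim = [r for r in records if not r.is_supplementary and r.tname != "*"]
    usable = []
    for r in prim:
        if r.qname not in truth:
            warnings.warn(f"query {r.qname!r} has no truth interval; excluded")
            continue
        usable.append(r)
    out: dict[float, dict[int, float]] = {}
    for frac in fractions:
        out[frac] = {}
        for mq in mapq_thresholds:
            subset = [r for r in usable if r.mapq >= mq]
            if not subset:
                out[frac][mq] = float("nan")
                continue
            ncorr = 0
            for r in subset:
                ts, te = truth[r.qname]
                ov = min(te, r.target_end) - max(ts, r.pos)
                if te > ts and ov / (te - ts) >= frac:
                    ncorr += 1
            out[frac][mq] = ncorr / len(subset)
    return out


# ---------------------------------------------------------------------------
# SAM / PAF emission
# ---------------------------------------------------------------------------


def sam_header(targets: dict[str, str], program: str = "cgmap") -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for tid, seq in targets.items():
        lines.append(f"@SQ\tSN:{tid}\tLN:{len(seq)}")
    lines.append(f"@PG\tID:{program}\tPN:{program}\tVN:0.1.0")
    return "\n".join(lines) + "\n"


def to_sam(rec: AlignmentRecord) -> str:
    if rec.tname == "*":
        return f"{rec.qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.seq or '*'}\t*\n"
    flag = 0
    if rec.strand == "-":
        flag |= 16
    if rec.is_supplementary:
        flag |= 2048
    return (
        f"{rec.qname}\t{flag}\t{rec.tname}\t{rec.pos + 1}\t{rec.mapq}\t"
        f"{rec.cigar_string()}\t*\t0\t0\t{rec.seq or '*'}\t*\tAS:i:{int(rec.score)}\n"
    )


def to_paf(rec: AlignmentRecord, target_length: int) -> str:
    if rec.tname == "*":
        return ""
    lead = rec.cigar[0][0] if rec.cigar and rec.cigar[0][1] == "S" else 0
    trail = rec.cigar[-1][0] if rec.cigar and rec.cigar[-1][1] == "S" else 0
    if rec.strand == "+":
        q_start, q_end = lead, rec.query_length - trail
    else:
        q_start, q_end = trail, rec.query_length - lead
    matches = sum(n for n, op in rec.cigar if op == "M")
    alnlen = sum(n for n, op in rec.cigar if op in "MID")
    return (
        f"{rec.qname}\t{rec.query_length}\t{q_start}\t{q_end}\t{rec.strand}\t"
        f"{rec.tname}\t{target_length}\t{rec.pos}\t{rec.target_end}\t"
        f"{matches}\t{alnlen}\t{rec.mapq}\n"
    )
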