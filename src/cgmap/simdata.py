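"""Seeded simulation of toy genomes, structural variants, and noisy reads.

All fixtures used by the aligner's tests are generated here rather than
shipped: a random (optionally repeat-salted) genome; a mutated haplotype
carrying non-overlapping structural variants — insertions, deletions,
inversions, inversions flanked by deletions (INVDEL) and inverted
duplications (INVDUP); and reads sampled from the haplotype with a
per-base multinomial error model (mismatch/insertion/deletion), random
strand, and a truth interval on the haplotype plus its projection onto
the source genome.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .index import revcomp

__all__ = [
    "SvSpec",
    "ReadModel",
    "SimulatedRead",
    "simulate_genome",
    "apply_svs",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SvSpec:
    """One structural variant on the source genome.

    ``pos`` is the 0-based position of the event; ``length`` its size in
    bases (>= 50 for SV semantics).  INVDEL is an inversion flanked by
    two deletions of ``flank_del`` bases each; INVDUP inserts the
    reverse complement of the ``length`` bases at ``pos`` immediately
    after them.
    """

    type: str  # INS | DEL | INV | INVDEL | INVDUP
    pos: int
    length: int
    flank_del: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("INS", "DEL", "INV", "INVDEL", "INVDUP"):
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.length < 50:
            raise ValueError("SV length must be >= 50")
        if self.type == "INVDEL" and self.flank_del <= 0:
            raise ValueError("INVDEL requires positive flanking deletion length")

    def source_span(self) -> tuple[int, int]:
        """Half-open interval of source bases the event touches."""
        if self.type == "INS":
            return (self.pos, self.pos)
        if self.type == "INVDEL":
            return (self.pos - self.flank_del, self.pos + self.length + self.flank_del)
        return (self.pos, self.pos + self.length)


@dataclass(frozen=True)
class ReadModel:
    """Read length and error-rate envelope of a sequencing technology."""

    mean_length: int = 1500
    min_length: int = 1000
    max_length: int = 2000
    mismatch: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.mismatch, self.insertion, self.deletion):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must be in [0, 1)")

    @property
    def total_error(self) -> float:
        return self.mismatch + self.insertion + self.deletion

    @classmethod
    def preset(cls, name: str, **kw) -> "ReadModel":
        presets = {
            # total error rates: HiFi <1%, CLR ~20%, ONT ~12%
            "hifi": dict(mismatch=0.002, insertion=0.004, deletion=0.004),
            "clr": dict(mismatch=0.06, insertion=0.08, deletion=0.06),
            "ont": dict(mismatch=0.05, insertion=0.03, deletion=0.04),
            "perfect": dict(mismatch=0.0, insertion=0.0, deletion=0.0),
        }
        if name not in presets:
            raise ValueError(f"unknown read preset {name!r}")
        return cls(**{**presets[name], **kw})


@dataclass
class SimulatedRead:
    name: str
    seq: str
    strand: str
    hap_start: int  # truth interval on the (mutated) haplotype
    hap_end: int
    src_start: int  # projection onto the source genome
    src_end: int


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    repeat_unit: str | None = None,
    repeat_copies: int = 0,
    repeat_at: int | None = None,
) -> str:
    """I.i.d. random genome of ``length`` bases at GC fraction ``gc``.

    Optionally a tandem array (``repeat_unit`` x ``repeat_copies``) is
    spliced in at ``repeat_at`` (default: the middle), replacing the
    random bases there.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    if repeat_unit and repeat_copies > 0:
        array = repeat_unit * repeat_copies
        at = repeat_at if repeat_at is not None else (length - len(array)) // 2
        if at < 0 or at + len(array) > length:
            raise ValueError("repeat array does not fit in the genome")
        seq = seq[:at] + array + seq[at + len(array) :]
    return seq


def apply_svs(genome: str, specs: Sequence[SvSpec], seed: int = 0) -> tuple[str, list[dict]]:
    """Apply non-overlapping SVs; returns (haplotype, truth table).

    The haplotype is assembled with a single left-to-right pass over the
    source genome, replacing each event's source span with its derived
    sequence, so every truth row carries exact coordinates on both the
    source genome and the haplotype.
    """
    ordered = sorted(specs, key=lambda s: s.source_span())
    for a, b in zip(ordered, ordered[1:]):
        if a.source_span()[1] > b.source_span()[0]:
            raise ValueError("SV specs overlap on the source genome")
    for s in ordered:
        lo, hi = s.source_span()
        if lo < 0 or hi > len(genome):
            raise ValueError("SV outside the genome")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    truth: list[dict] = []
    cursor = 0  # source coordinate
    hap_pos = 0  # haplotype coordinate
    for spec in ordered:
        lo, hi = spec.source_span()
        parts.append(genome[cursor:lo])
        hap_pos += lo - cursor
        p, L = spec.pos, spec.length
        if spec.type == "INS":
            repl = "".join(_BASES[rng.integers(0, 4, size=L)])
            derived = (hap_pos, hap_pos + L)
        elif spec.type == "DEL":
            repl = ""
            derived = (hap_pos, hap_pos)
        elif spec.type == "INV":
            repl = revcomp(genome[p : p + L])
            derived = (hap_pos, hap_pos + L)
        elif spec.type == "INVDEL":
            repl = revcomp(genome[p : p + L])
            derived = (hap_pos, hap_pos + L)
        else:  # INVDUP: inverted copy inserted immediately after the source
            repl = genome[p : p + L] + revcomp(genome[p : p + L])
            derived = (hap_pos + L, hap_pos + 2 * L)
        truth.append(
            {
                "type": spec.type,
                "src_start": lo,
                "src_end": hi,
                "hap_start": derived[0],
                "hap_end": derived[1],
                "hap_region_start": hap_pos,
                "hap_region_end": hap_pos + len(repl),
                "length": L,
            }
        )
        parts.append(repl)
        hap_pos += len(repl)
        cursor = hi
    parts.append(genome[cursor:])
    return "".join(parts), truth


def _project_to_source(pos: int, truth: Sequence[dict]) -> int:
    """Map a haplotype coordinate back onto the source genome."""
    delta = 0
    for row in truth:
        if row["hap_region_end"] <= pos:
            src_len = row["src_end"] - row["src_start"]
            hap_len = row["hap_region_end"] - row["hap_region_start"]
            delta += src_len - hap_len
        elif row["hap_region_start"] <= pos:
            off = pos - row["hap_region_start"]
            return row["src_start"] + min(off, row["src_end"] - row["src_start"])
    return pos + delta


def simulate_reads(
    genome: str,
    model: ReadModel,
    depth: float,
    seed: int = 0,
    truth: Sequence[dict] = (),
) -> list[SimulatedRead]:
    """Uniformly sampled reads with multinomial per-base errors.

    Read count is ``depth * len(genome) / mean_length``; lengths uniform
    in [min_length, max_length]; strand random.  The truth interval is
    the source span on ``genome`` (the haplotype handed in); when a
    ``truth`` table is supplied the interval is also projected onto the
    source genome the haplotype derives from.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * len(genome) / model.mean_length))
    reads: list[SimulatedRead] = []
    p_err = [model.mismatch, model.insertion, model.deletion]
    p_none = 1.0 - sum(p_err)
    for ri in range(n_reads):
        length = int(rng.integers(model.min_length, model.max_length + 1))
        length = min(length, len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        template = genome[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        if model.total_error > 0:
            events = rng.choice(4, size=len(template), p=[p_none] + p_err)
            out = []
            for base, ev in zip(template, events):
                if ev == 0:
                    out.append(base)
                elif ev == 1:  # mismatch
                    out.append(_BASES[(("ACGT".index(base)) + int(rng.integers(1, 4))) % 4])
                elif ev == 2:  # insertion before the base
                    out.append(_BASES[int(rng.integers(0, 4))])
                    out.append(base)
                # ev == 3: deletion, emit nothing
            seq = "".join(out)
        else:
            seq = template
        if not seq:
            continue
        src_s = _project_to_source(start, truth) if truth else start
        src_e = _project_to_source(start + length, truth) if truth else start + length
        reads.append(
            SimulatedRead(
                name=f"read{ri}",
                seq=seq,
                strand=strand,
                hap_start=start,
                hap_end=start + length,
                src_start=src_s,
                src_end=src_e,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, reads: Iterable[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_tsv(path: str, reads: Iterable[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstrand\thap_start\thap_end\tsrc_start\tsrc_end\n")
        for r in reads:
            fh.write(
                f"{r.name}\t{r.strand}\t{r.hap_start}\t{r.hap_end}\t{r.src_start}\t{r.src_end}\n"
            )
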