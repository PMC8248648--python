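"""Minimizer computation, adaptive index filtering, anchor matching."""

from __future__ import annotations

from collections import Counter

import pytest

from cgmap.index import (
    Anchor,
    GlobalIndex,
    GlobalIndexParams,
    LocalIndexParams,
    build_global_index,
    build_local_index,
    compute_minimizers,
    match_anchors,
    revcomp,
)
from cgmap.index import _canonical_minimizers

from conftest import random_seq


def brute_minimizers(seq: str, k: int, w: int) -> list[tuple[int, str]]:
    """Window-by-window enumeration oracle for the minimizer scheme."""

    def canon(s: str) -> str:
        return min(s, revcomp(s))

    total = len(seq) - k + 1
    if total < 1:
        return []
    valid = [i for i in range(total) if all(c in "ACGT" for c in seq[i : i + k])]
    picks: set[int] = set()
    for ws in range(0, max(1, total - w + 1)):
        window = [i for i in valid if ws <= i < min(total, ws + w)]
        if window:
            picks.add(min(window, key=lambda i: (canon(seq[i : i + k]), i)))
    return sorted((i, canon(seq[i : i + k])) for i in picks)


# ---------------------------------------------------------------------------
# compute_minimizers
# ---------------------------------------------------------------------------


def test_sequence_shorter_than_k_yields_nothing():
    assert compute_minimizers("ACG", 5, 3) == []


def test_homopolymer_reports_only_its_kmer():
    mins = compute_minimizers("AAAAAAAA", 3, 3)
    assert mins and all(kmer == "AAA" for _, kmer in mins)


@pytest.mark.parametrize("k,w", [(3, 2), (5, 4), (7, 5), (11, 3)])
def test_minimizers_match_bruteforce_window_scan(rng, k, w):
    for _ in range(12):
        seq = random_seq(rng, rng.randint(k, 300))
        if rng.random() < 0.4:
            cut = rng.randrange(len(seq))
            seq = seq[:cut] + "N" * rng.randint(1, 4) + seq[cut:]
        assert compute_minimizers(seq, k, w) == brute_minimizers(seq, k, w)


def test_pure_n_sequence_has_no_minimizers():
    assert compute_minimizers("N" * 60, 5, 4) == []


# ---------------------------------------------------------------------------
# build_global_index
# ---------------------------------------------------------------------------


def test_unique_genome_survives_both_filters_intact(rng):
    # all k-mers unique and generous caps: stages 2 and 3 remove nothing
    seq = random_seq(rng, 400)
    params = GlobalIndexParams(k=13, w=5, f_max=50, n_max=500, w_genome=400)
    idx = build_global_index({"c": seq}, params)
    mins = _canonical_minimizers(seq, 13, 5)
    indexed = {(pos, code) for code, hits in idx.entries.items() for _, pos, _ in hits}
    assert indexed == {(pos, code) for pos, code, _ in mins}


def test_high_multiplicity_kmers_are_removed(rng):
    unit = "ACGTTGCAAC"
    seq = unit * 50 + random_seq(rng, 1500)
    params = GlobalIndexParams(k=7, w=4, f_max=10, n_max=1000, w_genome=500)
    idx = build_global_index({"c": seq}, params)
    mult = Counter(code for _, code, _ in _canonical_minimizers(seq, 7, 4))
    assert all(mult[code] <= 10 for code in idx.entries)
    # the repeat's own k-mers exceeded the cap and must be absent
    over = {code for code, n in mult.items() if n > 10}
    assert over and not (over & set(idx.entries))


def test_interval_thinning_keeps_lowest_multiplicity_first(rng):
    seq = random_seq(rng, 1000)
    params = GlobalIndexParams(k=9, w=4, f_max=100, n_max=5, w_genome=250)
    idx = build_global_index({"c": seq}, params)
    mins = _canonical_minimizers(seq, 9, 4)
    mult = Counter(code for _, code, _ in mins)
    survivors = [(pos, code) for pos, code, _ in mins if mult[code] <= 100]
    kept = sorted((pos, code) for code, hits in idx.entries.items() for _, pos, _ in hits)
    for interval in range(0, 1000 // 250):
        in_int = [e for e in survivors if e[0] // 250 == interval]
        kept_int = [e for e in kept if e[0] // 250 == interval]
        want = sorted(sorted(in_int, key=lambda e: (mult[e[1]], e[0]))[:5])
        assert kept_int == want
        assert len(kept_int) <= 5


def test_empty_reference_is_rejected():
    with pytest.raises(ValueError):
        build_global_index({"c": ""}, GlobalIndexParams(k=5, w=3, w_genome=100))


def test_index_round_trips_through_sidecar_file(rng, tmp_path):
    seq = random_seq(rng, 600)
    idx = build_global_index({"c": seq}, GlobalIndexParams(k=9, w=4, w_genome=300))
    path = str(tmp_path / "ref.cgi")
    idx.save(path)
    loaded = GlobalIndex.load(path)
    assert loaded.params == idx.params
    assert loaded.entries == idx.entries
    assert loaded.target_lengths == idx.target_lengths


# ---------------------------------------------------------------------------
# match_anchors
# ---------------------------------------------------------------------------


def test_exact_substring_yields_constant_forward_diagonal(rng):
    ref = random_seq(rng, 3000)
    idx = build_global_index({"c": ref}, GlobalIndexParams(k=11, w=5, f_max=100, n_max=50, w_genome=200))
    q = ref[700:1200]
    anchors = match_anchors(q, idx)
    assert anchors
    fwd = [a for a in anchors if a.strand == "+"]
    assert {a.f for a in fwd} == {700}
    assert anchors == sorted(anchors, key=lambda a: (a.tid, a.x, a.y))


def test_reverse_complement_query_yields_reverse_anchors(rng):
    ref = random_seq(rng, 3000)
    idx = build_global_index({"c": ref}, GlobalIndexParams(k=11, w=5, f_max=100, n_max=50, w_genome=200))
    q = revcomp(ref[1500:2000])
    anchors = match_anchors(q, idx)
    assert anchors and all(a.strand == "-" for a in anchors)
    assert len({a.r for a in anchors}) == 1
    # soundness by direct string comparison
    for a in anchors:
        assert q[a.x : a.x + a.k] == revcomp(ref[a.y : a.y + a.k])


def test_pure_n_query_yields_no_anchors(rng):
    ref = random_seq(rng, 2000)
    idx = build_global_index({"c": ref}, GlobalIndexParams(k=11, w=5, w_genome=200))
    assert match_anchors("N" * 300, idx) == []


# ---------------------------------------------------------------------------
# build_local_index
# ---------------------------------------------------------------------------


def test_short_sequence_gets_a_single_tile(rng):
    li = build_local_index(random_seq(rng, 500), LocalIndexParams(7, 5, 1000))
    assert li.n_tiles == 1


def test_tile_count_follows_ceiling_rule(rng):
    li = build_local_index(random_seq(rng, 2500), LocalIndexParams(7, 5, 1000))
    assert li.n_tiles == 3
    assert [t * 1000 for t in range(3)] == [0, 1000, 2000]


def test_tiles_union_equals_per_tile_minimizers(rng):
    seq = random_seq(rng, 2500)
    params = LocalIndexParams(7, 5, 1000)
    li = build_local_index(seq, params)
    got = sorted(
        (pos, code)
        for table in li.tiles
        for code, hits in table.items()
        for pos, _ in hits
    )
    want = []
    for t in range(3):
        sub = seq[t * 1000 : (t + 1) * 1000]
        for pos, code, _ in _canonical_minimizers(sub, 7, 5):
            want.append((t * 1000 + pos, code))
    assert got == sorted(want)
    # absolute positions are valid coordinates
    assert all(0 <= pos < len(seq) for pos, _ in got)


def test_local_params_must_be_finer_than_global():
    with pytest.raises(ValueError):
        LocalIndexParams(15, 10, 1000).check_against(GlobalIndexParams(k=15, w=10))
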