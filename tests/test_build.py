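"""Block construction: filtering, chaining (against a brute-force oracle),
block assembly, overlap resolution, pairwise builds and multi-species
intersection."""

import numpy as np
import pytest

from syntenykit.core import Anchor, BuildParams, Interval, Placement, SyntenyBlock, SyntenyMap
from syntenykit.build import (
    build_pairwise,
    chain_anchors,
    filter_anchors,
    intersect_maps,
    resolve_overlaps,
    runs_to_blocks,
)
from syntenykit.simulate import anchors_from_truth, simulate_karyotype, simulate_rearrangements


def A(rs, re, ts, te, orient="+", rc="chr1", tc="X"):
    return Anchor(Interval(rc, rs, re), Interval(tc, ts, te), orient)


# ------------------------------------------------------------------ filtering

def test_filter_drops_short_side_and_sorts():
    params = BuildParams(resolution=1000, max_gap=1000, min_anchor=100)
    anchors = [A(0, 50, 0, 120), A(300, 500, 0, 200), A(100, 300, 0, 200)]
    kept = filter_anchors(anchors, params)
    assert [a.ref.start for a in kept] == [100, 300]  # short one gone, sorted


def test_filter_with_zero_min_anchor_is_identity_up_to_sort():
    params = BuildParams(resolution=1000, max_gap=1000, min_anchor=0)
    anchors = [A(300, 500, 0, 200), A(0, 50, 0, 120)]
    assert sorted(map(id, filter_anchors(anchors, params))) == sorted(map(id, anchors))


def test_filter_tie_broken_by_larger_ref_end_first():
    params = BuildParams(resolution=1000, min_anchor=0)
    a_small, a_big = A(100, 200, 0, 100), A(100, 400, 200, 500)
    assert filter_anchors([a_small, a_big], params) == [a_big, a_small]


# ------------------------------------------------------------------- chaining

def oracle_chain(anchors, params):
    """Exhaustive chaining oracle for small anchor sets.

    Explores the full choice tree: each anchor, in reference order, either
    joins any compatible open run (pairwise constraints re-derived here
    from first principles) or opens a new one. Among all complete valid
    partitions it returns the one preferred by the rank order used at each
    step — join the most recently opened compatible run before opening a
    new run — which is the partition the production sweep must produce.
    """

    def pair_ok(p, q):
        if q.ref.chrom != p.ref.chrom or q.tgt.chrom != p.tgt.chrom:
            return False
        if q.orientation != p.orientation:
            return False
        if not (q.ref.start > p.ref.start and q.ref.end > p.ref.end):
            return False
        if not (-params.min_anchor <= q.ref.start - p.ref.end <= params.max_gap):
            return False
        if p.orientation == "+":
            if not (q.tgt.start > p.tgt.start and q.tgt.end > p.tgt.end):
                return False
            gap = q.tgt.start - p.tgt.end
        else:
            if not (q.tgt.start < p.tgt.start and q.tgt.end < p.tgt.end):
                return False
            gap = p.tgt.start - q.tgt.end
        return -params.min_anchor <= gap <= params.max_gap

    best: list[list] = []

    def explore(i, runs, choices, best_choices):
        if i == len(anchors):
            if not best_choices or choices > best_choices[0]:
                best_choices.clear()
                best_choices.append(list(choices))
                best.clear()
                best.extend([list(r) for r in runs])
            return
        a = anchors[i]
        # rank: joining run k scores k (later-opened is larger); new run
        # scores -1, so it is only preferred when no join is possible
        options = [k for k in range(len(runs)) if pair_ok(runs[k][-1], a)]
        for k in sorted(options, reverse=True) + [None]:
            if k is None:
                runs.append([a])
                choices.append(-1)
                explore(i + 1, runs, choices, best_choices)
                choices.pop()
                runs.pop()
            else:
                runs[k].append(a)
                choices.append(k)
                explore(i + 1, runs, choices, best_choices)
                choices.pop()
                runs[k].pop()

    explore(0, [], [], [])
    # order runs by first anchor reference position, as the sweep reports
    best.sort(key=lambda r: (r[0].ref.chrom, r[0].ref.start))
    return best


def random_small_anchor_set(seed, n_max=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    anchors = []
    pos = 0
    for _ in range(n):
        pos += int(rng.integers(0, 400))
        span = int(rng.integers(100, 500))
        rc = "chr1" if rng.random() < 0.8 else "chr2"
        tc = "X" if rng.random() < 0.7 else "Y"
        orient = "+" if rng.random() < 0.7 else "-"
        ts = int(rng.integers(0, 3000))
        anchors.append(Anchor(Interval(rc, pos, pos + span),
                              Interval(tc, ts, ts + span), orient))
        pos += span
    return anchors


@pytest.mark.parametrize("seed", range(60))
def test_greedy_chaining_matches_bruteforce_oracle(seed):
    params = BuildParams(resolution=100, max_gap=500, min_anchor=50)
    anchors = filter_anchors(random_small_anchor_set(seed), params)
    got = [r.anchors for r in chain_anchors(anchors, params)]
    assert got == oracle_chain(anchors, params)


def test_two_forward_anchors_chain_within_gap():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    a = A(100, 200, 1000, 1100)
    b = A(250, 350, 1150, 1250)
    (run,) = chain_anchors([a, b], params)
    assert run.anchors == [a, b]


def test_target_chromosome_change_splits():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    runs = chain_anchors([A(100, 200, 1000, 1100), A(250, 350, 1150, 1250, tc="Y")], params)
    assert len(runs) == 2


def test_orientation_change_splits():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    runs = chain_anchors([A(100, 200, 1000, 1100, "+"), A(250, 350, 900, 990, "-")], params)
    assert len(runs) == 2


def test_noise_anchor_does_not_sever_a_run():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    a = A(100, 200, 1000, 1100)
    noise = A(210, 320, 9000, 9110, tc="Y")
    b = A(250, 350, 1150, 1250)
    runs = chain_anchors(filter_anchors([a, noise, b], params), params)
    member_sets = [run.anchors for run in runs]
    assert [a, b] in member_sets and [noise] in member_sets


# ------------------------------------------------------------ blocks & spans

def test_run_to_block_span_arithmetic_and_resolution_filter():
    a = A(100, 200, 1000, 1100)
    b = A(250, 350, 1150, 1250)
    lo = BuildParams(resolution=200, max_gap=1000, min_anchor=10)
    (run,) = chain_anchors([a, b], lo)
    (block,) = runs_to_blocks([run], lo)
    assert block.ref == Interval("chr1", 100, 350)
    assert block.placements["_"].tgt == Interval("X", 1000, 1250)
    hi = BuildParams(resolution=300, max_gap=1000, min_anchor=10)
    assert runs_to_blocks([run], hi) == []


def test_single_anchor_run_survives_when_large_enough():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    (run,) = chain_anchors([A(0, 150, 0, 150)], params)
    assert len(runs_to_blocks([run], params)) == 1
    assert runs_to_blocks([], params) == []


# ----------------------------------------------------------- overlap removal

def B(rs, re, ts=None, te=None, orient="+", rc="chr1", tc="X", bid=1):
    ts = rs if ts is None else ts
    te = re if te is None else te
    return SyntenyBlock(bid, Interval(rc, rs, re), {"_": Placement(Interval(tc, ts, te), orient)})


def test_smaller_block_trimmed_on_reference():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    b1 = B(0, 500, 0, 500)
    b2 = B(400, 1200, 2000, 2800, bid=2)
    out = resolve_overlaps([b1, b2], params)
    assert [b.ref for b in out] == [Interval("chr1", 0, 400), Interval("chr1", 400, 1200)]


def test_disjoint_blocks_unchanged():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    b1, b2 = B(0, 300, 0, 300), B(400, 800, 400, 800, bid=2)
    assert [b.ref for b in resolve_overlaps([b1, b2], params)] == [b1.ref, b2.ref]


def test_trim_below_resolution_drops_block():
    params = BuildParams(resolution=300, max_gap=1000, min_anchor=10)
    b1 = B(0, 300, 1000, 1300)
    b2 = B(100, 450, 2000, 2350, bid=2)
    out = resolve_overlaps([b1, b2], params)
    # b2 is the larger block; b1 is trimmed to [0,100) and dropped (< 300)
    assert [b.ref for b in out] == [Interval("chr1", 100, 450)]


def test_target_side_overlaps_also_resolved():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=10)
    b1 = B(0, 500, 1000, 1500)
    b2 = B(1000, 1800, 1400, 2200, bid=2, rc="chr2")
    out = resolve_overlaps([b1, b2], params)
    t1 = out[0].placements["_"].tgt
    t2 = out[1].placements["_"].tgt
    assert t1.end <= t2.start  # no residual overlap on target X


# ------------------------------------------------------------ pairwise build

def test_noise_free_anchors_recover_planted_truth(truth, clean_anchors, params, karyotype):
    built = build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype)
    assert built.blocks == truth.truth_map.blocks
    built.validate(karyotype)


def test_all_anchors_below_min_anchor_gives_empty_map():
    params = BuildParams(resolution=100, max_gap=1000, min_anchor=500)
    m = build_pairwise([A(0, 100, 0, 100)], "r", "t", params)
    assert m.blocks == []


def test_duplicated_anchor_list_builds_identical_map(truth, clean_anchors, params, karyotype):
    once = build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype)
    twice = build_pairwise(list(clean_anchors) * 2, "ref", "tgt", params, ref_karyotype=karyotype)
    assert twice.blocks == once.blocks


def test_blocks_contained_in_anchor_union(truth, clean_anchors, params, karyotype):
    built = build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype)
    by_chrom = {}
    for a in clean_anchors:
        by_chrom.setdefault(a.ref.chrom, []).append(a.ref)
    for b in built.blocks:
        lo = min(iv.start for iv in by_chrom[b.ref.chrom])
        hi = max(iv.end for iv in by_chrom[b.ref.chrom])
        assert lo <= b.ref.start and b.ref.end <= hi


def test_all_blocks_meet_resolution_on_both_genomes(truth, clean_anchors, karyotype):
    params = BuildParams(resolution=120_000)
    built = build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype)
    for b in built.blocks:
        assert b.ref.length >= params.resolution
        assert b.placements["tgt"].tgt.length >= params.resolution


def test_coverage_monotone_in_resolution(clean_anchors, karyotype):
    covered = []
    for res in (10_000, 50_000, 100_000, 200_000):
        p = BuildParams(resolution=res, max_gap=10_000)
        m = build_pairwise(clean_anchors, "ref", "tgt", p, ref_karyotype=karyotype)
        covered.append(sum(b.ref.length for b in m.blocks))
    assert covered == sorted(covered, reverse=True)


def test_determinism_byte_identical_unified_output(tmp_path, clean_anchors, params, karyotype):
    from syntenykit.io import write_unified
    pa, pb = tmp_path / "a.synteny", tmp_path / "b.synteny"
    write_unified(build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype), pa)
    write_unified(build_pairwise(clean_anchors, "ref", "tgt", params, ref_karyotype=karyotype), pb)
    assert pa.read_bytes() == pb.read_bytes()


# ------------------------------------------------------------- intersection

def one_block_map(target, rs, re, ts, te, orient="+"):
    return SyntenyMap("r", [target], [
        SyntenyBlock(1, Interval("chr1", rs, re),
                     {target: Placement(Interval("c", ts, te), orient)})
    ], resolution=300)


def test_identical_pairwise_maps_intersect_unchanged():
    params = BuildParams(resolution=300)
    m = intersect_maps(
        [one_block_map("T1", 0, 1000, 0, 1000), one_block_map("T2", 0, 1000, 500, 1500)],
        params,
    )
    (b,) = m.blocks
    assert b.ref == Interval("chr1", 0, 1000)
    assert b.placements["T1"].tgt == Interval("c", 0, 1000)
    assert b.placements["T2"].tgt == Interval("c", 500, 1500)


def test_partial_overlap_keeps_common_segment_only():
    params = BuildParams(resolution=300)
    m = intersect_maps(
        [one_block_map("T1", 0, 1000, 0, 1000), one_block_map("T2", 500, 1500, 500, 1500)],
        params,
    )
    (b,) = m.blocks
    assert b.ref == Interval("chr1", 500, 1000)
    # T1's placement is cropped in proportion to the reference crop
    assert b.placements["T1"].tgt == Interval("c", 500, 1000)
    assert b.placements["T2"].tgt == Interval("c", 500, 1000)


def test_common_segment_below_resolution_is_dropped():
    params = BuildParams(resolution=300)
    m = intersect_maps(
        [one_block_map("T1", 0, 700, 0, 700), one_block_map("T2", 500, 1500, 0, 1000)],
        params,
    )
    assert m.blocks == []


def test_reference_mismatch_rejected():
    m1 = one_block_map("T1", 0, 1000, 0, 1000)
    m2 = one_block_map("T2", 0, 1000, 0, 1000)
    m2.reference = "other"
    with pytest.raises(Exception):
        intersect_maps([m1, m2], BuildParams(resolution=300))


def test_inverted_placement_cropped_from_opposite_end():
    params = BuildParams(resolution=300)
    m = intersect_maps(
        [one_block_map("T1", 0, 1000, 0, 1000, orient="-"),
         one_block_map("T2", 500, 1500, 500, 1500)],
        params,
    )
    (b,) = m.blocks
    assert b.ref == Interval("chr1", 500, 1000)
    # reference tail [500,1000) of an inverted block maps to target head
    assert b.placements["T1"].tgt == Interval("c", 0, 500)
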