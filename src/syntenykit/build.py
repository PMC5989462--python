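"""Synteny block construction from pairwise alignment anchors.

The construction follows the classic conserved-segment recipe: filter tiny
anchors, chain collinear anchors greedily left-to-right along the reference,
turn each maximal run into a candidate block, drop blocks below the
resolution on either genome, and resolve residual overlaps so the final map
partitions cleanly. A separate step intersects several pairwise maps into
multi-species blocks conserved across every target.

Chaining rule: walking anchors in reference order on one reference
chromosome, an anchor extends a run iff it has the same target chromosome
and orientation as the run, its reference gap to the run's last anchor is
within ``[-min_anchor, max_gap]``, its target gap measured in the
orientation's direction of travel is within the same band, and the target
keeps advancing (forward for ``+``, backward for ``-``). An incompatible
anchor opens a new run without closing compatible ones, so noise anchors
cannot sever a collinear run; every anchor lands in exactly one run.
Small overlaps (up to ``min_anchor`` bp, as chain trimming produces) are
tolerated as negative gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import (
    Anchor,
    BuildParams,
    Interval,
    Karyotype,
    Placement,
    SyntenyBlock,
    SyntenyError,
    SyntenyMap,
    crop_placement,
    natural_chrom_key,
)

__all__ = [
    "ChainRun",
    "filter_anchors",
    "chain_anchors",
    "runs_to_blocks",
    "resolve_overlaps",
    "build_pairwise",
    "intersect_maps",
]


@dataclass
class ChainRun:
    """A maximal collinear run of anchors sharing one target chromosome and
    orientation, with reference intervals strictly increasing and target
    intervals advancing in the orientation's direction."""

    anchors: list[Anchor]

    @property
    def orientation(self) -> str:
        return self.anchors[0].orientation

    @property
    def tgt_chrom(self) -> str:
        return self.anchors[0].tgt.chrom


def _anchor_sort_key(karyotype: Karyotype | None):
    if karyotype is not None:
        def key(a: Anchor):
            return (karyotype.order_index(a.ref.chrom), a.ref.start, -a.ref.end)
    else:
        def key(a: Anchor):
            return (natural_chrom_key(a.ref.chrom), a.ref.start, -a.ref.end)
    return key


def filter_anchors(
    anchors: Sequence[Anchor],
    params: BuildParams,
    ref_karyotype: Karyotype | None = None,
) -> list[Anchor]:
    """Drop anchors whose shorter side is below ``min_anchor`` and sort the
    survivors by reference position (ties: larger span first)."""
    kept = [
        a for a in anchors
        if min(a.ref.length, a.tgt.length) >= params.min_anchor
    ]
    kept.sort(key=_anchor_sort_key(ref_karyotype))
    return kept


def _can_join(last: Anchor, nxt: Anchor, params: BuildParams) -> bool:
    if nxt.tgt.chrom != last.tgt.chrom or nxt.orientation != last.orientation:
        return False
    if nxt.ref.chrom != last.ref.chrom:
        return False
    # reference must keep advancing
    if nxt.ref.start <= last.ref.start or nxt.ref.end <= last.ref.end:
        return False
    ref_gap = nxt.ref.start - last.ref.end
    if not (-params.min_anchor <= ref_gap <= params.max_gap):
        return False
    if last.orientation == "+":
        if nxt.tgt.start <= last.tgt.start or nxt.tgt.end <= last.tgt.end:
            return False
        tgt_gap = nxt.tgt.start - last.tgt.end
    else:
        if nxt.tgt.start >= last.tgt.start or nxt.tgt.end >= last.tgt.end:
            return False
        tgt_gap = last.tgt.start - nxt.tgt.end
    return -params.min_anchor <= tgt_gap <= params.max_gap


def chain_anchors(anchors: Sequence[Anchor], params: BuildParams) -> list[ChainRun]:
    """Greedy left-to-right chaining of filtered, reference-sorted anchors
    into maximal collinear runs.

    Several runs may be open at once: each anchor joins the most recently
    opened run it is compatible with, else opens a new run, so a lone
    off-diagonal anchor starts its own (typically size-filtered) run
    instead of severing a collinear one. A run closes once the sweep has
    moved more than ``max_gap`` past its reference end (or left its
    chromosome); every anchor lands in exactly one run. Runs are returned
    in order of their first anchor.
    """
    runs: list[ChainRun] = []
    open_runs: list[list[Anchor]] = []  # in opening order

    def close(run: list[Anchor]) -> None:
        runs.append(ChainRun(run))

    for a in anchors:
        still_open: list[list[Anchor]] = []
        for run in open_runs:
            last = run[-1]
            if last.ref.chrom != a.ref.chrom or a.ref.start - last.ref.end > params.max_gap:
                close(run)
            else:
                still_open.append(run)
        open_runs = still_open
        for run in reversed(open_runs):  # most recently opened first
            if _can_join(run[-1], a, params):
                run.append(a)
                break
        else:
            open_runs.append([a])
    for run in open_runs:
        close(run)
    runs.sort(key=lambda r: (natural_chrom_key(r.anchors[0].ref.chrom), r.anchors[0].ref.start))
    return runs


def runs_to_blocks(runs: Sequence[ChainRun], params: BuildParams) -> list[SyntenyBlock]:
    """Turn each run into a candidate block (reference span = first anchor
    start to last anchor end; target span = enclosing span of member target
    intervals) and drop blocks below the resolution on either genome.
    Target genome name is left for the caller; placements are keyed by a
    placeholder resolved in :func:`build_pairwise`."""
    blocks: list[SyntenyBlock] = []
    for run in runs:
        first, last = run.anchors[0], run.anchors[-1]
        ref = Interval(first.ref.chrom, first.ref.start, last.ref.end)
        tgt = Interval(
            run.tgt_chrom,
            min(a.tgt.start for a in run.anchors),
            max(a.tgt.end for a in run.anchors),
        )
        if ref.length < params.resolution or tgt.length < params.resolution:
            continue
        blocks.append(SyntenyBlock(1, ref, {"_": Placement(tgt, run.orientation)}))
    for i, b in enumerate(blocks, start=1):
        b.block_id = i
    return blocks


def _trim_ref(block: SyntenyBlock, new_start: int, new_end: int) -> SyntenyBlock | None:
    """Trim a pairwise block's reference interval, cropping its single
    placement proportionally; returns None when nothing sensible remains."""
    if new_end - new_start < 1:
        return None
    (key, placement), = block.placements.items()
    new_pl = crop_placement(block.ref, placement, new_start, new_end)
    return SyntenyBlock(
        block.block_id,
        Interval(block.ref.chrom, new_start, new_end),
        {key: new_pl},
    )


def _trim_tgt(block: SyntenyBlock, new_tstart: int, new_tend: int) -> SyntenyBlock | None:
    """Trim a pairwise block on the target side, cropping the reference
    proportionally (orientation-aware)."""
    if new_tend - new_tstart < 1:
        return None
    (key, placement), = block.placements.items()
    tgt = placement.tgt
    scale = block.ref.length / tgt.length
    if placement.orientation == "+":
        rs = block.ref.start + round((new_tstart - tgt.start) * scale)
        re_ = block.ref.start + round((new_tend - tgt.start) * scale)
    else:
        rs = block.ref.start + round((tgt.end - new_tend) * scale)
        re_ = block.ref.start + round((tgt.end - new_tstart) * scale)
    rs = max(block.ref.start, min(rs, block.ref.end - 1))
    re_ = max(rs + 1, min(re_, block.ref.end))
    return SyntenyBlock(
        block.block_id,
        Interval(block.ref.chrom, rs, re_),
        {key: Placement(Interval(tgt.chrom, new_tstart, new_tend), placement.orientation)},
    )


def _ok(block: SyntenyBlock, params: BuildParams) -> bool:
    placement = next(iter(block.placements.values()))
    return (block.ref.length >= params.resolution
            and placement.tgt.length >= params.resolution)


def _ref_sweep(blocks: list[SyntenyBlock], params: BuildParams) -> tuple[list[SyntenyBlock], bool]:
    """One left-to-right sweep resolving reference overlaps: the block with
    the smaller reference span is trimmed by the overlap; blocks trimmed
    below the resolution are dropped."""
    changed = False
    out: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda b: (natural_chrom_key(b.ref.chrom), b.ref.start, -b.ref.length)):
        while b is not None and out:
            a = out[-1]
            if a.ref.chrom != b.ref.chrom or b.ref.start >= a.ref.end:
                break
            changed = True
            if b.ref.length <= a.ref.length:
                # b is the smaller block; its left edge carries the overlap
                new_start = min(a.ref.end, b.ref.end)
                b = _trim_ref(b, new_start, b.ref.end) if new_start < b.ref.end else None
                if b is not None and not _ok(b, params):
                    b = None
            else:
                out.pop()
                na = _trim_ref(a, a.ref.start, b.ref.start) if a.ref.start < b.ref.start else None
                if na is not None and _ok(na, params):
                    out.append(na)
        if b is not None and _ok(b, params):
            out.append(b)
        else:
            changed = True
    return out, changed


def _tgt_key(b: SyntenyBlock):
    p = next(iter(b.placements.values()))
    return (natural_chrom_key(p.tgt.chrom), p.tgt.start, -p.tgt.length)


def _tgt_sweep(blocks: list[SyntenyBlock], params: BuildParams) -> tuple[list[SyntenyBlock], bool]:
    """Resolve overlaps of two blocks on the same target chromosome by
    trimming the one with the smaller *reference* span on the overlapping
    target side (the reference is cropped proportionally)."""
    changed = False
    out: list[SyntenyBlock] = []
    for b in sorted(blocks, key=_tgt_key):
        while b is not None and out:
            a = out[-1]
            pa = next(iter(a.placements.values()))
            pb = next(iter(b.placements.values()))
            if pa.tgt.chrom != pb.tgt.chrom or pb.tgt.start >= pa.tgt.end:
                break
            changed = True
            if b.ref.length <= a.ref.length:
                new_tstart = min(pa.tgt.end, pb.tgt.end)
                b = _trim_tgt(b, new_tstart, pb.tgt.end) if new_tstart < pb.tgt.end else None
                if b is not None and not _ok(b, params):
                    b = None
            else:
                out.pop()
                na = _trim_tgt(a, pa.tgt.start, pb.tgt.start) if pa.tgt.start < pb.tgt.start else None
                if na is not None and _ok(na, params):
                    out.append(na)
        if b is not None and _ok(b, params):
            out.append(b)
        else:
            changed = True
    return out, changed


def resolve_overlaps(blocks: Sequence[SyntenyBlock], params: BuildParams) -> list[SyntenyBlock]:
    """Deterministically resolve overlaps among candidate pairwise blocks on
    the reference and on each target chromosome (smaller-reference-span
    block is trimmed; trims below the resolution drop the block). Iterates
    ref/target sweeps to a fixpoint."""
    out = list(blocks)
    for _ in range(10):
        out, ch1 = _ref_sweep(out, params)
        out, ch2 = _tgt_sweep(out, params)
        if not (ch1 or ch2):
            break
    out.sort(key=lambda b: (natural_chrom_key(b.ref.chrom), b.ref.start))
    return out


def build_pairwise(
    anchors: Sequence[Anchor],
    reference: str,
    target: str,
    params: BuildParams,
    ref_karyotype: Karyotype | None = None,
) -> SyntenyMap:
    """Full pairwise construction: filter -> chain -> blocks -> overlap
    resolution -> renumber."""
    filtered = filter_anchors(anchors, params, ref_karyotype)
    runs = chain_anchors(filtered, params)
    blocks = runs_to_blocks(runs, params)
    blocks = resolve_overlaps(blocks, params)
    renamed: list[SyntenyBlock] = []
    for b in blocks:
        (placement,) = b.placements.values()
        renamed.append(SyntenyBlock(b.block_id, b.ref, {target: placement}))
    smap = SyntenyMap(reference=reference, targets=[target], blocks=renamed,
                      resolution=params.resolution)
    smap.sort_blocks(ref_karyotype)
    smap.renumber()
    return smap


def intersect_maps(pairwise_maps: Sequence[SyntenyMap], params: BuildParams) -> SyntenyMap:
    """Intersect pairwise maps sharing one reference into multi-species
    blocks.

    The reference is partitioned at the union of all pairwise block
    boundaries; a segment survives iff it is covered by exactly one block in
    EVERY pairwise map and spans at least the resolution. Each surviving
    segment becomes a multi-species block whose per-target placements are
    the covering blocks' target intervals cropped linearly in proportion to
    the reference crop (direction respecting orientation).
    """
    if not pairwise_maps:
        raise SyntenyError("need at least one pairwise map")
    reference = pairwise_maps[0].reference
    for m in pairwise_maps[1:]:
        if m.reference != reference:
            raise SyntenyError(
                f"reference genome mismatch: {m.reference!r} vs {reference!r}"
            )
    targets: list[str] = []
    for m in pairwise_maps:
        for t in m.targets:
            if t in targets:
                raise SyntenyError(f"target genome {t!r} appears in two pairwise maps")
            targets.append(t)

    boundaries: dict[str, set[int]] = {}
    for m in pairwise_maps:
        for b in m.blocks:
            boundaries.setdefault(b.ref.chrom, set()).update((b.ref.start, b.ref.end))

    blocks: list[SyntenyBlock] = []
    for chrom in sorted(boundaries, key=natural_chrom_key):
        cuts = sorted(boundaries[chrom])
        for s, e in zip(cuts, cuts[1:]):
            if e - s < params.resolution:
                continue
            placements: dict[str, Placement] = {}
            covered_everywhere = True
            for m in pairwise_maps:
                cover = [
                    b for b in m.blocks
                    if b.ref.chrom == chrom and b.ref.start <= s and e <= b.ref.end
                ]
                if len(cover) != 1:
                    covered_everywhere = False
                    break
                block = cover[0]
                for tgt_genome, pl in block.placements.items():
                    placements[tgt_genome] = crop_placement(block.ref, pl, s, e)
            if covered_everywhere:
                blocks.append(SyntenyBlock(1, Interval(chrom, s, e), placements))

    smap = SyntenyMap(reference=reference, targets=targets, blocks=blocks,
                      resolution=params.resolution)
    smap.sort_blocks()
    smap.renumber()
    return smap
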