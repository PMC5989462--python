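"""Synthetic genomes, rearrangements with exact ground truth, noisy anchors
and genes with known block relationships.

The simulator evolves a copy of a reference karyotype through a list of
breakpoint operations (inversion, reciprocal translocation, fission, fusion,
transposition). Operations are bp-preserving — no sequence is gained or
lost — so the resulting segment correspondence tiles the reference exactly
and the induced truth :class:`~syntenykit.core.SyntenyMap` is exact by
construction: one block per maximal segment unbroken by any breakpoint,
with ``-`` orientation where an odd number of inversions covered it and the
correct target chromosome after translocations/fissions/fusions.

From a truth map the generators emit:

* anchors — each truth block tiled by alternating anchor/gap stretches
  (lengths uniform within +-50% of the requested means), with optional
  boundary jitter, uniformly placed spurious anchors, and random anchor
  drop-out;
* genes — with intended classes: "conserved" strictly inside one block,
  "broken" straddling one or two internal block boundaries (including a
  three-block spanner when geometry permits), "unplaced" inside reference
  gaps not covered by any block.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Anchor,
    Gene,
    Interval,
    Karyotype,
    Placement,
    SyntenyBlock,
    SyntenyError,
    SyntenyMap,
)

__all__ = [
    "RearrangementOp",
    "TruthSet",
    "simulate_karyotype",
    "random_ops",
    "simulate_rearrangements",
    "anchors_from_truth",
    "genes_from_truth",
    "mask_blocks",
    "recovery_stats",
    "random_synteny_map",
    "random_chain_text",
]


@dataclass(frozen=True)
class RearrangementOp:
    """One rearrangement applied to the evolving target genome.

    ``loci`` are breakpoint coordinates on the evolving genome, in the
    operation's own terms:

    * inversion:      (chrom_index, start, end) — invert [start, end)
    * translocation:  (chrom_a, pos_a, chrom_b, pos_b) — reciprocal tail swap
    * fission:        (chrom_index, pos) — split into two chromosomes
    * fusion:         (chrom_a, chrom_b) — append b onto the end of a
    * transposition:  (chrom_index, start, end, dest_chrom, dest_pos) —
      cut [start, end) and reinsert at dest_pos (dest coordinates taken
      after the cut when on the same chromosome)
    """

    kind: str
    loci: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "fission", "fusion", "transposition"):
            raise SyntenyError(f"unknown rearrangement kind {self.kind!r}")


@dataclass
class _Segment:
    """A run of target sequence copied from the reference: ref coordinates
    plus a sign (+1 forward, -1 inverted)."""

    ref_chrom: str
    start: int
    end: int
    sign: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """A simulated reference/target pair with its exact block decomposition."""

    ref_karyotype: Karyotype
    tgt_karyotype: Karyotype
    truth_map: SyntenyMap
    ops: list[RearrangementOp] = field(default_factory=list)
    genes: list[tuple[Gene, str]] = field(default_factory=list)


def simulate_karyotype(
    n_chroms: int,
    length_range: tuple[int, int],
    seed: int,
    genome_name: str = "ref",
) -> Karyotype:
    """A karyotype of ``n_chroms`` chromosomes named chr1..chrN with lengths
    drawn uniformly from ``length_range`` (inclusive)."""
    lo, hi = int(length_range[0]), int(length_range[1])
    if n_chroms < 1 or lo < 1 or hi < lo:
        raise SyntenyError("need n_chroms >= 1 and 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_chroms)
    return Karyotype(genome_name, [(f"chr{i+1}", int(L)) for i, L in enumerate(lengths)])


# ---------------------------------------------------------------------------
# genome evolution


def _split_at(chrom: list[_Segment], pos: int) -> int:
    """Split the segment containing target-coordinate ``pos`` so that a
    segment boundary falls exactly at ``pos``; returns the segment index
    starting at ``pos``."""
    off = 0
    for i, seg in enumerate(chrom):
        if off == pos:
            return i
        if off < pos < off + seg.length:
            d = pos - off
            if seg.sign > 0:
                left = _Segment(seg.ref_chrom, seg.start, seg.start + d, seg.sign)
                right = _Segment(seg.ref_chrom, seg.start + d, seg.end, seg.sign)
            else:
                # inverted segment: the first d target bp come from the ref tail
                left = _Segment(seg.ref_chrom, seg.end - d, seg.end, seg.sign)
                right = _Segment(seg.ref_chrom, seg.start, seg.end - d, seg.sign)
            chrom[i : i + 1] = [left, right]
            return i + 1
        off += seg.length
    if off == pos:
        return len(chrom)
    raise SyntenyError(f"breakpoint {pos} outside chromosome of length {off}")


def _chrom_len(chrom: list[_Segment]) -> int:
    return sum(s.length for s in chrom)


def _apply_op(genome: list[list[_Segment]], op: RearrangementOp) -> None:
    kind, loci = op.kind, op.loci
    if kind == "inversion":
        ci, a, b = loci
        chrom = genome[ci]
        if not (0 < a < b < _chrom_len(chrom)):
            raise SyntenyError(f"inversion breakpoints {a},{b} outside chromosome")
        i = _split_at(chrom, a)
        j = _split_at(chrom, b)
        mid = chrom[i:j][::-1]
        for s in mid:
            s.sign = -s.sign
        chrom[i:j] = mid
    elif kind == "translocation":
        ca, pa, cb, pb = loci
        if ca == cb:
            raise SyntenyError("reciprocal translocation needs two distinct chromosomes")
        a_chrom, b_chrom = genome[ca], genome[cb]
        ia = _split_at(a_chrom, pa)
        ib = _split_at(b_chrom, pb)
        tail_a, tail_b = a_chrom[ia:], b_chrom[ib:]
        genome[ca] = a_chrom[:ia] + tail_b
        genome[cb] = b_chrom[:ib] + tail_a
    elif kind == "fission":
        ci, pos = loci
        chrom = genome[ci]
        if not (0 < pos < _chrom_len(chrom)):
            raise SyntenyError(f"fission breakpoint {pos} outside chromosome")
        i = _split_at(chrom, pos)
        genome[ci] = chrom[:i]
        genome.append(chrom[i:])
    elif kind == "fusion":
        ca, cb = loci
        if ca == cb:
            raise SyntenyError("fusion needs two distinct chromosomes")
        genome[ca] = genome[ca] + genome[cb]
        del genome[cb]
    elif kind == "transposition":
        ci, a, b, cd, pos = loci
        chrom = genome[ci]
        i = _split_at(chrom, a)
        j = _split_at(chrom, b)
        piece = chrom[i:j]
        del chrom[i:j]
        dest = genome[cd]
        k = _split_at(dest, pos)
        dest[k:k] = piece


def _merge_adjacent(chrom: list[_Segment]) -> list[_Segment]:
    """Re-merge consecutive segments that were split by a breakpoint later
    undone (same ref chromosome, same sign, ref-adjacent in the direction of
    travel) so truth blocks are maximal."""
    out: list[_Segment] = []
    for seg in chrom:
        if out:
            prev = out[-1]
            if prev.ref_chrom == seg.ref_chrom and prev.sign == seg.sign:
                if seg.sign > 0 and seg.start == prev.end:
                    prev.end = seg.end
                    continue
                if seg.sign < 0 and seg.end == prev.start:
                    prev.start = seg.start
                    continue
        out.append(_Segment(seg.ref_chrom, seg.start, seg.end, seg.sign))
    return out


def random_ops(
    karyotype: Karyotype,
    n_ops: int,
    seed: int,
    min_segment: int = 100_000,
    kinds: tuple[str, ...] = ("inversion", "inversion", "translocation", "fission", "fusion"),
) -> list[RearrangementOp]:
    """Draw a random, valid operation list against an evolving copy of the
    karyotype. Breakpoints keep at least ``min_segment`` bp away from every
    existing segment boundary so all truth blocks stay comfortably above a
    build resolution below that value. Operations that cannot be placed
    (e.g. fusion on a single-chromosome genome, or no room left between
    breakpoints) are skipped and retried with another kind; the returned
    list may therefore be shorter than ``n_ops`` on crowded genomes.
    """
    rng = np.random.default_rng(seed)
    genome: list[list[_Segment]] = [
        [_Segment(name, 0, length, +1)] for name, length in karyotype.chromosomes
    ]
    ops: list[RearrangementOp] = []

    def legal_positions(chrom: list[_Segment]) -> list[int]:
        bounds = [0]
        off = 0
        for s in chrom:
            off += s.length
            bounds.append(off)
        total = bounds[-1]
        # sample candidates and keep those min_segment away from all bounds
        cands = rng.integers(1, total, size=64) if total > 1 else np.array([], dtype=int)
        return [int(p) for p in cands if all(abs(int(p) - b) >= min_segment for b in bounds)]

    attempts = 0
    while len(ops) < n_ops and attempts < n_ops * 20:
        attempts += 1
        kind = kinds[int(rng.integers(0, len(kinds)))]
        n_chrom = len(genome)
        if kind == "inversion":
            ci = int(rng.integers(0, n_chrom))
            pos = legal_positions(genome[ci])
            pos = [p for p in pos]
            if len(pos) < 2:
                continue
            a, b = sorted(rng.choice(pos, size=2, replace=False))
            if b - a < min_segment:
                continue
            op = RearrangementOp("inversion", (ci, int(a), int(b)))
        elif kind == "translocation":
            if n_chrom < 2:
                continue
            ca, cb = rng.choice(n_chrom, size=2, replace=False)
            pa = legal_positions(genome[int(ca)])
            pb = legal_positions(genome[int(cb)])
            if not pa or not pb:
                continue
            op = RearrangementOp(
                "translocation", (int(ca), int(pa[0]), int(cb), int(pb[0]))
            )
        elif kind == "fission":
            ci = int(rng.integers(0, n_chrom))
            pos = legal_positions(genome[ci])
            if not pos:
                continue
            op = RearrangementOp("fission", (ci, int(pos[0])))
        elif kind == "fusion":
            if n_chrom < 2:
                continue
            ca, cb = rng.choice(n_chrom, size=2, replace=False)
            op = RearrangementOp("fusion", (int(ca), int(cb)))
        else:  # transposition
            ci = int(rng.integers(0, n_chrom))
            pos = legal_positions(genome[ci])
            if len(pos) < 2:
                continue
            a, b = sorted(rng.choice(pos, size=2, replace=False))
            if b - a < min_segment:
                continue
            cd = int(rng.integers(0, n_chrom))
            # destination position chosen after the cut
            dest_len = _chrom_len(genome[ci]) - (b - a) if cd == ci else _chrom_len(genome[cd])
            if dest_len <= 2 * min_segment:
                continue
            p = int(rng.integers(min_segment, dest_len - min_segment + 1))
            op = RearrangementOp("transposition", (ci, int(a), int(b), cd, p))
        _apply_op(genome, op)
        ops.append(op)
    return ops


def simulate_rearrangements(
    karyotype: Karyotype,
    ops: list[RearrangementOp] | None = None,
    n_ops: int | None = None,
    seed: int = 0,
    min_segment: int = 100_000,
    tgt_name: str = "tgt",
) -> TruthSet:
    """Apply rearrangements to a copy of ``karyotype`` and return the target
    karyotype together with the exact truth map induced by the breakpoints
    (one block per maximal unbroken segment)."""
    if ops is None:
        ops = random_ops(karyotype, n_ops or 0, seed, min_segment=min_segment)
    genome: list[list[_Segment]] = [
        [_Segment(name, 0, length, +1)] for name, length in karyotype.chromosomes
    ]
    for op in ops:
        _apply_op(genome, op)
    genome = [_merge_adjacent(c) for c in genome if c]

    tgt_chroms: list[tuple[str, int]] = []
    blocks: list[SyntenyBlock] = []
    for idx, chrom in enumerate(genome):
        tname = f"chr{idx+1}"
        tgt_chroms.append((tname, _chrom_len(chrom)))
        off = 0
        for seg in chrom:
            placement = Placement(
                Interval(tname, off, off + seg.length),
                "+" if seg.sign > 0 else "-",
            )
            blocks.append(
                SyntenyBlock(1, Interval(seg.ref_chrom, seg.start, seg.end), {tgt_name: placement})
            )
            off += seg.length

    tgt_karyotype = Karyotype(tgt_name, tgt_chroms)
    truth = SyntenyMap(reference=karyotype.genome_name, targets=[tgt_name], blocks=blocks)
    truth.sort_blocks(karyotype)
    truth.renumber()
    return TruthSet(karyotype, tgt_karyotype, truth, ops=list(ops))


# ---------------------------------------------------------------------------
# anchors


def anchors_from_truth(
    truth_map: SyntenyMap,
    tgt_karyotype: Karyotype | None = None,
    anchor_len_mean: int = 20_000,
    gap_mean: int = 2_000,
    jitter_sd: int = 0,
    spurious_rate: float = 0.0,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> list[Anchor]:
    """Emit alignment anchors consistent with a truth map.

    Each truth block is tiled with alternating anchors and gaps whose
    lengths are uniform within +-50% of the means; the first anchor starts
    at the block's reference start and the last one is extended to end at
    the block's reference end, so with zero noise the anchor extremes equal
    the truth boundaries exactly. Anchors inherit the block's orientation
    and linear reference-to-target mapping. Jitter perturbs anchor edges by
    a clipped normal (|delta| <= 3*jitter_sd) while staying inside the
    block. ``spurious_rate`` adds that fraction of uniformly placed random
    anchors (needs ``tgt_karyotype``); ``drop_rate`` removes that fraction
    of true anchors at random.
    """
    if not (anchor_len_mean > 0 and gap_mean >= 0):
        raise SyntenyError("anchor_len_mean must be positive and gap_mean nonnegative")
    if not (0 <= spurious_rate <= 1 and 0 <= drop_rate <= 1):
        raise SyntenyError("rates must be in [0, 1]")
    if spurious_rate > 0 and tgt_karyotype is None:
        raise SyntenyError("spurious anchors need a target karyotype")
    rng = np.random.default_rng(seed)
    (target,) = truth_map.targets
    anchors: list[Anchor] = []

    def draw(mean: int) -> int:
        lo, hi = max(1, int(mean * 0.5)), max(1, int(mean * 1.5))
        return int(rng.integers(lo, hi + 1))

    for block in truth_map.blocks:
        pl = block.placements[target]
        rs, re_ = block.ref.start, block.ref.end
        edges: list[tuple[int, int]] = []
        pos = rs
        while pos < re_:
            a_len = draw(anchor_len_mean)
            a_end = min(pos + a_len, re_)
            edges.append((pos, a_end))
            pos = a_end + (draw(gap_mean) if gap_mean > 0 else 0)
        # pin the last anchor to the block's right edge
        if edges and edges[-1][1] != re_:
            s, _ = edges[-1]
            edges[-1] = (s, re_)
        for a_start, a_end in edges:
            if jitter_sd > 0:
                lim = 3 * jitter_sd
                ds = int(np.clip(rng.normal(0, jitter_sd), -lim, lim))
                de = int(np.clip(rng.normal(0, jitter_sd), -lim, lim))
                a_start = min(max(rs, a_start + ds), re_ - 1)
                a_end = max(a_start + 1, min(re_, a_end + de))
            # linear mapping into the target placement (block spans are
            # bp-identical on both genomes by construction)
            if pl.orientation == "+":
                t_start = pl.tgt.start + (a_start - rs)
                t_end = pl.tgt.start + (a_end - rs)
            else:
                t_start = pl.tgt.start + (re_ - a_end)
                t_end = pl.tgt.start + (re_ - a_start)
            anchors.append(
                Anchor(
                    Interval(block.ref.chrom, a_start, a_end),
                    Interval(pl.tgt.chrom, t_start, t_end),
                    pl.orientation,
                )
            )

    if drop_rate > 0:
        keep = rng.random(len(anchors)) >= drop_rate
        anchors = [a for a, k in zip(anchors, keep) if k]

    if spurious_rate > 0:
        ref_chroms: dict[str, int] = {}
        for b in truth_map.blocks:
            ref_chroms[b.ref.chrom] = max(ref_chroms.get(b.ref.chrom, 0), b.ref.end)
        ref_names = sorted(ref_chroms)
        n_spur = int(round(spurious_rate * len(anchors)))
        for _ in range(n_spur):
            rc = ref_names[int(rng.integers(0, len(ref_names)))]
            length = draw(anchor_len_mean)
            rstart = int(rng.integers(0, max(1, ref_chroms[rc] - length)))
            tc, tlen = tgt_karyotype.chromosomes[int(rng.integers(0, len(tgt_karyotype.chromosomes)))]
            tstart = int(rng.integers(0, max(1, tlen - length)))
            orient = "+" if rng.random() < 0.5 else "-"
            anchors.append(
                Anchor(Interval(rc, rstart, rstart + length),
                       Interval(tc, tstart, tstart + length), orient)
            )
    return anchors


# ---------------------------------------------------------------------------
# genes


def mask_blocks(truth_map: SyntenyMap, fraction: float, seed: int = 0) -> SyntenyMap:
    """Remove a random fraction of blocks (at least one when fraction > 0),
    leaving uncovered reference gaps — the substrate for 'unplaced' genes."""
    if not (0 <= fraction <= 1):
        raise SyntenyError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth_map.blocks)
    n_drop = max(1, int(round(fraction * n))) if fraction > 0 else 0
    drop = set(rng.choice(n, size=min(n_drop, n), replace=False).tolist())
    kept = [b for i, b in enumerate(truth_map.blocks) if i not in drop]
    out = SyntenyMap(truth_map.reference, list(truth_map.targets),
                     kept, truth_map.resolution)
    out.renumber()
    return out


def genes_from_truth(
    truth_map: SyntenyMap,
    n_per_class: int,
    seed: int = 0,
    ref_karyotype: Karyotype | None = None,
    min_gene: int = 500,
) -> list[tuple[Gene, str]]:
    """Plant genes with known classes against a (possibly masked) map:
    'conserved' genes strictly inside one block, 'broken' genes straddling
    internal boundaries between reference-adjacent blocks (with one
    three-block spanner when geometry permits), and 'unplaced' genes inside
    uncovered reference gaps. Strands alternate; raises when a class cannot
    be placed (e.g. no uncovered gap for 'unplaced')."""
    if not truth_map.blocks:
        raise SyntenyError("cannot plant genes against an empty map")
    if n_per_class == 0:
        return []
    rng = np.random.default_rng(seed)
    target = truth_map.targets[0]
    blocks = [b for b in truth_map.blocks if target in b.placements]
    genes: list[tuple[Gene, str]] = []
    strand_cycle = ["+", "-"]
    counter = 0

    def next_strand() -> str:
        nonlocal counter
        s = strand_cycle[counter % 2]
        counter += 1
        return s

    # conserved: strictly inside one block
    wide = [b for b in blocks if b.ref.length >= 4 * min_gene]
    if len(wide) == 0:
        raise SyntenyError("no block wide enough for conserved genes")
    for i in range(n_per_class):
        b = wide[int(rng.integers(0, len(wide)))]
        start = int(rng.integers(b.ref.start + 1, b.ref.end - min_gene))
        genes.append(
            (Gene(Interval(b.ref.chrom, start, start + min_gene), f"CONS{i+1}", next_strand()),
             "conserved")
        )

    # broken: straddle boundaries between blocks adjacent on the reference
    adj: list[tuple[SyntenyBlock, ...]] = []
    triples: list[tuple[SyntenyBlock, ...]] = []
    for a, b in zip(blocks, blocks[1:]):
        if a.ref.chrom == b.ref.chrom and a.ref.end == b.ref.start:
            adj.append((a, b))
    for a, b, c in zip(blocks, blocks[1:], blocks[2:]):
        if (a.ref.chrom == b.ref.chrom == c.ref.chrom
                and a.ref.end == b.ref.start and b.ref.end == c.ref.start):
            triples.append((a, b, c))
    if not adj:
        raise SyntenyError("no adjacent block pair to plant broken genes on")
    for i in range(n_per_class):
        if i == 0 and triples:
            a, b, c = triples[int(rng.integers(0, len(triples)))]
            start = max(a.ref.start + 1, b.ref.start - min_gene)
            end = min(c.ref.end - 1, b.ref.end + min_gene)
            name = f"BROK{i+1}_SPAN3"
        else:
            a, b = adj[int(rng.integers(0, len(adj)))]
            cut = a.ref.end
            start = max(a.ref.start + 1, cut - min_gene)
            end = min(b.ref.end - 1, cut + min_gene)
            name = f"BROK{i+1}"
        genes.append((Gene(Interval(a.ref.chrom, start, end), name, next_strand()), "broken"))

    # unplaced: inside uncovered reference gaps
    gaps: list[Interval] = []
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.ref.start)
        for a, b in zip(bs, bs[1:]):
            if b.ref.start - a.ref.end >= 3 * min_gene:
                gaps.append(Interval(chrom, a.ref.end + min_gene, b.ref.start - min_gene))
        if ref_karyotype is not None and chrom in ref_karyotype:
            L = ref_karyotype.length_of(chrom)
            if L - bs[-1].ref.end >= 3 * min_gene:
                gaps.append(Interval(chrom, bs[-1].ref.end + min_gene, L - min_gene))
            if bs[0].ref.start >= 3 * min_gene:
                gaps.append(Interval(chrom, min_gene, bs[0].ref.start - min_gene))
    if not gaps:
        raise SyntenyError(
            "no uncovered reference gap for unplaced genes; mask blocks first"
        )
    for i in range(n_per_class):
        g = gaps[int(rng.integers(0, len(gaps)))]
        start = int(rng.integers(g.start, max(g.start + 1, g.end - min_gene)))
        genes.append(
            (Gene(Interval(g.chrom, start, min(start + min_gene, g.end)), f"UNPL{i+1}", next_strand()),
             "unplaced")
        )
    return genes


def recovery_stats(truth_map: SyntenyMap, built_map: SyntenyMap, tol: int) -> dict:
    """Score a built map against the planted truth.

    A truth block counts as recovered when built blocks compatible with it
    (same target chromosome and orientation, overlapping its reference
    interval) exist and their leftmost start and rightmost end each fall
    within ``tol`` bp of the truth boundaries. A built block is chimeric
    when it overlaps two truth blocks that disagree in target chromosome
    or orientation. Returns n_truth, n_recovered and n_chimeric.
    """
    from .core import overlap_len

    (target,) = truth_map.targets
    n_recovered = 0
    for tb in truth_map.blocks:
        pl = tb.placements[target]
        compat = [
            b for b in built_map.blocks
            if b.ref.chrom == tb.ref.chrom
            and overlap_len(b.ref, tb.ref) > 0
            and b.placements[target].tgt.chrom == pl.tgt.chrom
            and b.placements[target].orientation == pl.orientation
        ]
        if not compat:
            continue
        if (abs(min(b.ref.start for b in compat) - tb.ref.start) <= tol
                and abs(max(b.ref.end for b in compat) - tb.ref.end) <= tol):
            n_recovered += 1
    n_chimeric = 0
    for b in built_map.blocks:
        sigs = {
            (t.placements[target].tgt.chrom, t.placements[target].orientation)
            for t in truth_map.blocks
            if overlap_len(b.ref, t.ref) > 0
        }
        if len(sigs) > 1:
            n_chimeric += 1
    return {
        "n_truth": len(truth_map.blocks),
        "n_recovered": n_recovered,
        "n_chimeric": n_chimeric,
    }


# ---------------------------------------------------------------------------
# format-fuzzing fixtures


def random_synteny_map(
    seed: int,
    n_blocks: int = 8,
    n_targets: int = 2,
    reference: str = "refG",
) -> SyntenyMap:
    """A random but invariant-satisfying multi-species map, for round-trip
    and rendering tests."""
    rng = np.random.default_rng(seed)
    targets = [f"tgt{i+1}" for i in range(n_targets)]
    blocks: list[SyntenyBlock] = []
    pos = {f"chr{c+1}": 0 for c in range(3)}
    chroms = sorted(pos)
    for i in range(n_blocks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        gap = int(rng.integers(0, 5_000))
        span = int(rng.integers(1_000, 50_000))
        start = pos[chrom] + gap
        pos[chrom] = start + span
        placements = {}
        for t in targets:
            tc = f"chr{int(rng.integers(1, 4))}"
            ts = int(rng.integers(0, 1_000_000))
            tl = int(rng.integers(1_000, 50_000))
            placements[t] = Placement(
                Interval(tc, ts, ts + tl), "+" if rng.random() < 0.5 else "-"
            )
        blocks.append(SyntenyBlock(1, Interval(chrom, start, start + span), placements))
    smap = SyntenyMap(reference=reference, targets=targets, blocks=blocks, resolution=0)
    smap.sort_blocks()
    smap.renumber()
    return smap


def random_chain_text(seed: int, n_chains: int = 3) -> str:
    """Random syntactically valid UCSC chain text plus the total of its data
    line sizes, for conservation checks on the chain reader. Returns the
    text; the expected reference-span total is recomputable as the sum of
    all block sizes, which equals what :func:`~syntenykit.io.read_chain`
    must conserve."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for ci in range(n_chains):
        n_blocks = int(rng.integers(1, 8))
        sizes = rng.integers(50, 5_000, size=n_blocks)
        dts = rng.integers(0, 2_000, size=n_blocks - 1) if n_blocks > 1 else []
        dqs = rng.integers(0, 2_000, size=n_blocks - 1) if n_blocks > 1 else []
        t_span = int(np.sum(sizes) + np.sum(dts))
        q_span = int(np.sum(sizes) + np.sum(dqs))
        t_start = int(rng.integers(0, 10_000))
        q_start = int(rng.integers(0, 10_000))
        t_size = t_start + t_span + int(rng.integers(0, 10_000))
        q_size = q_start + q_span + int(rng.integers(0, 10_000))
        q_strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            f"chain {int(rng.integers(1, 10_000))} chrT{ci % 2 + 1} {t_size} + "
            f"{t_start} {t_start + t_span} chrQ{ci % 3 + 1} {q_size} {q_strand} "
            f"{q_start} {q_start + q_span} {ci + 1}"
        )
        for bi in range(n_blocks - 1):
            out.append(f"{int(sizes[bi])} {int(dts[bi])} {int(dqs[bi])}")
        out.append(f"{int(sizes[-1])}")
        out.append("")
    return "\n".join(out) + "\n"
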