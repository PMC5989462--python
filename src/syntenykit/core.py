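"""Domain types and interval arithmetic shared by the whole package.

All genomic coordinates are 0-based half-open internally. File formats that
use other conventions (1-based inclusive, reverse-strand query coordinates)
are converted at the I/O boundary and nowhere else.

A :class:`SyntenyBlock` is one conserved segment: an interval on the
reference genome plus one placed interval per target genome, each with an
orientation. Orientation ``-`` means the target interval — always stored on
the forward strand of the target chromosome — is inverted relative to the
reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Interval",
    "Anchor",
    "Karyotype",
    "Placement",
    "SyntenyBlock",
    "SyntenyMap",
    "Gene",
    "Cytoband",
    "BuildParams",
    "overlap_len",
    "to_file_coords",
    "from_file_coords",
    "natural_chrom_key",
]

_STRANDS = ("+", "-")


class SyntenyError(ValueError):
    """Domain invariant violation."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise SyntenyError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise SyntenyError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # debugging convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_len(a: Interval, b: Interval) -> int:
    """Length (bp) of the intersection of two intervals; 0 if disjoint or on
    different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def to_file_coords(iv: Interval) -> tuple[str, int, int]:
    """Convert an internal interval to the 1-based inclusive convention used
    by the unified synteny file."""
    return (iv.chrom, iv.start + 1, iv.end)


def from_file_coords(chrom: str, start: int, end: int) -> Interval:
    """Inverse of :func:`to_file_coords`; rejects inverted or non-positive
    1-based ranges."""
    if start < 1:
        raise SyntenyError(f"1-based start must be >= 1, got {start}")
    if start > end:
        raise SyntenyError(f"inverted 1-based range {start}-{end}")
    return Interval(chrom, start - 1, end)


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_chrom_key(name: str) -> tuple:
    """Sort key placing chr2 before chr10 and chr22 before chrX."""
    parts = _NAT_SPLIT.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Anchor:
    """One (near-)ungapped pairwise alignment match: an interval on the
    reference, an interval on the target, and a relative orientation."""

    ref: Interval
    tgt: Interval
    orientation: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in _STRANDS:
            raise SyntenyError(f"orientation must be + or -, got {self.orientation!r}")
        if self.score < 0:
            raise SyntenyError("anchor score must be nonnegative")


@dataclass
class Karyotype:
    """Ordered chromosome names and lengths for one genome assembly.

    The given order is authoritative: it drives sort order of blocks and the
    sector order of circular plots (chr1..chr22,chrX stays as written).
    """

    genome_name: str
    chromosomes: list[tuple[str, int]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, length in self.chromosomes:
            if name in seen:
                raise SyntenyError(f"duplicate chromosome {name!r} in karyotype")
            seen.add(name)
            if length < 1:
                raise SyntenyError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(n == chrom for n, _ in self.chromosomes)

    def order_index(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class Placement:
    """Where one block lands on one target genome."""

    tgt: Interval
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in _STRANDS:
            raise SyntenyError(f"orientation must be + or -, got {self.orientation!r}")


@dataclass
class SyntenyBlock:
    """One conserved segment: a reference interval plus per-target placements."""

    block_id: int
    ref: Interval
    placements: dict[str, Placement]

    def __post_init__(self) -> None:
        if self.block_id < 1:
            raise SyntenyError("block_id must be a positive integer")
        if not self.placements:
            raise SyntenyError("a synteny block needs at least one target placement")


@dataclass
class SyntenyMap:
    """The ordered set of blocks for one reference and target set at one
    resolution (resolution 0 marks maps imported from third-party tools)."""

    reference: str
    targets: list[str]
    blocks: list[SyntenyBlock] = field(default_factory=list)
    resolution: int = 0

    def sort_blocks(self, karyotype: Karyotype | None = None) -> None:
        """Sort blocks by reference position in-place. Chromosome order comes
        from the karyotype when given, else natural order (chr2 < chr10)."""
        if karyotype is not None:
            def chrom_key(c: str):
                return (karyotype.order_index(c),)
        else:
            chrom_key = natural_chrom_key
        self.blocks.sort(key=lambda b: (chrom_key(b.ref.chrom), b.ref.start, -b.ref.length))

    def renumber(self) -> None:
        for i, b in enumerate(self.blocks, start=1):
            b.block_id = i

    def validate(self, karyotype: Karyotype | None = None) -> None:
        """Raise on any violated invariant: placement keys outside the target
        list, duplicate block ids, overlapping or unsorted reference
        intervals, or coordinates past chromosome ends."""
        seen_ids: set[int] = set()
        by_chrom: dict[str, list[Interval]] = {}
        for b in self.blocks:
            if b.block_id in seen_ids:
                raise SyntenyError(f"duplicate block_id {b.block_id}")
            seen_ids.add(b.block_id)
            unknown = set(b.placements) - set(self.targets)
            if unknown:
                raise SyntenyError(f"block {b.block_id} places onto unknown targets {sorted(unknown)}")
            if karyotype is not None:
                if b.ref.chrom not in karyotype:
                    raise SyntenyError(f"block {b.block_id} on unknown chromosome {b.ref.chrom}")
                if b.ref.end > karyotype.length_of(b.ref.chrom):
                    raise SyntenyError(f"block {b.block_id} extends past end of {b.ref.chrom}")
            by_chrom.setdefault(b.ref.chrom, []).append(b.ref)
        for chrom, ivs in by_chrom.items():
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start < prev.end:
                    raise SyntenyError(
                        f"reference intervals overlap or are unsorted on {chrom}: {prev} then {cur}"
                    )

    def blocks_for(self, target: str) -> list[SyntenyBlock]:
        """Pairwise projection: the blocks that have a placement on `target`."""
        if target not in self.targets:
            raise KeyError(f"unknown target genome {target!r}")
        return [b for b in self.blocks if target in b.placements]


@dataclass(frozen=True)
class Gene:
    location: Interval
    name: str
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise SyntenyError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.name:
            raise SyntenyError("gene name must be non-empty")


@dataclass(frozen=True)
class Cytoband:
    location: Interval
    band_name: str
    stain: str


@dataclass(frozen=True)
class BuildParams:
    """Tunables of block construction.

    resolution
        Minimum block span (bp) required on the reference AND on each
        target; also the default for ``max_gap``. Smaller values yield more,
        finer blocks.
    max_gap
        Maximum joinable gap (bp) between consecutive anchors, measured on
        either genome. Defaults to ``resolution``.
    min_anchor
        Anchors whose shorter side is below this span (bp) are discarded
        before chaining; the same amount of overlap between consecutive
        anchors (e.g. from chain trimming) is tolerated.
    """

    resolution: int
    max_gap: int | None = None
    min_anchor: int = 100

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise SyntenyError("resolution must be positive")
        if self.max_gap is None:
            object.__setattr__(self, "max_gap", self.resolution)
        if self.max_gap <= 0:
            raise SyntenyError("max_gap must be positive")
        if self.min_anchor < 0:
            raise SyntenyError("min_anchor must be nonnegative")
        if self.max_gap < self.min_anchor:
            raise SyntenyError("max_gap must be >= min_anchor")


def crop_placement(ref: Interval, placement: Placement, seg_start: int, seg_end: int) -> Placement:
    """Linearly crop a target placement to the sub-interval
    ``[seg_start, seg_end)`` of the block's reference interval, respecting
    orientation (a ``-`` placement is cropped from the opposite end)."""
    if not (ref.start <= seg_start < seg_end <= ref.end):
        raise SyntenyError(
            f"segment [{seg_start},{seg_end}) not inside reference interval {ref}"
        )
    tgt = placement.tgt
    scale = tgt.length / ref.length
    if placement.orientation == "+":
        ns = tgt.start + round((seg_start - ref.start) * scale)
        ne = tgt.start + round((seg_end - ref.start) * scale)
    else:
        ns = tgt.start + round((ref.end - seg_end) * scale)
        ne = tgt.start + round((ref.end - seg_start) * scale)
    ns = max(tgt.start, min(ns, tgt.end - 1))
    ne = max(ns + 1, min(ne, tgt.end))
    return Placement(Interval(tgt.chrom, ns, ne), placement.orientation)
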