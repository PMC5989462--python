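"""Readers, writers and converters for every on-disk format the pipeline
touches.

Formats
-------
* ``chrom.sizes`` — two whitespace-separated columns: chromosome name, length.
* UCSC chain — pairwise alignment chains; each ungapped block becomes one
  :class:`~syntenykit.core.Anchor`. Reverse-strand query coordinates are
  converted to forward-strand coordinates here (``fwd_start = qSize - rev_end``).
* generic anchor / block TSVs — column layout described by a
  :class:`TableDialect`; presets ship for Satsuma, Cinteny and
  SyntenyTracker style exports, but every preset is data and can be
  overridden because those tools' layouts vary between versions.
* BED6 gene annotations and UCSC ``cytoBandIdeo`` tables.
* the unified synteny block definition file (defined below) — the package's
  canonical on-disk block format.

Unified synteny block definition format
---------------------------------------
Text, one record per block, blank line between records::

    >17
    hg38.chr2:1-500000 +
    mm10.chr1:100001-600000 -
    bosTau8.chr11:1-499000 +

Line 1 is ``>`` + block id. Line 2 is the reference placement, then one
line per target in map target order. Coordinates are 1-based inclusive;
the reference strand is always ``+`` (inversion is expressed only on
target placements). Genome and chromosome are separated by the first dot,
so genome names must not contain dots.

All TSV readers skip blank lines and ``#`` comments.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    Anchor,
    Cytoband,
    Gene,
    Interval,
    Karyotype,
    Placement,
    SyntenyBlock,
    SyntenyError,
    SyntenyMap,
    from_file_coords,
    natural_chrom_key,
    overlap_len,
    to_file_coords,
)

__all__ = [
    "TableDialect",
    "DIALECT_PRESETS",
    "read_chrom_sizes",
    "read_chain",
    "read_anchors_tsv",
    "write_anchors_tsv",
    "read_unified",
    "write_unified",
    "convert_third_party",
    "read_bed_genes",
    "write_bed_genes",
    "read_cytoband",
]


@dataclass(frozen=True)
class TableDialect:
    """Column layout of a tab/whitespace-separated anchor or block table.

    ``column_map`` maps roles (ref_chrom, ref_start, ref_end, tgt_chrom,
    tgt_start, tgt_end, orientation, and optionally score and block_id) to
    0-based column indices. ``coords`` is either ``"0-half-open"`` or
    ``"1-inclusive"``.
    """

    name: str
    column_map: dict[str, int]
    coords: str = "0-half-open"
    orientation_tokens: dict[str, str] = field(
        default_factory=lambda: {"+": "+", "-": "-"}
    )

    REQUIRED = ("ref_chrom", "ref_start", "ref_end", "tgt_chrom", "tgt_start", "tgt_end", "orientation")

    def __post_init__(self) -> None:
        missing = [r for r in self.REQUIRED if r not in self.column_map]
        if missing:
            raise SyntenyError(f"dialect {self.name!r} misses required roles {missing}")
        idx = list(self.column_map.values())
        if len(idx) != len(set(idx)):
            raise SyntenyError(f"dialect {self.name!r} maps two roles to one column")
        if self.coords not in ("0-half-open", "1-inclusive"):
            raise SyntenyError(f"unknown coordinate convention {self.coords!r}")

    def interval(self, chrom: str, start_tok: str, end_tok: str) -> Interval:
        start, end = int(start_tok), int(end_tok)
        if self.coords == "1-inclusive":
            return from_file_coords(chrom, start, end)
        return Interval(chrom, start, end)

    def strand(self, token: str) -> str:
        try:
            return self.orientation_tokens[token]
        except KeyError:
            raise SyntenyError(
                f"dialect {self.name!r}: unmapped orientation token {token!r}"
            ) from None


# Presets for the third-party exports the converter accepts. Satsuma chained
# summaries put the target (query) interval first and use 0-based half-open
# match coordinates; Cinteny and SyntenyTracker emit 1-based inclusive block
# tables with an explicit block id. Layouts differ between tool versions, so
# these are defaults to be overridden with an explicit column map if needed.
DIALECT_PRESETS: dict[str, TableDialect] = {
    "generic": TableDialect(
        "generic",
        {
            "ref_chrom": 0, "ref_start": 1, "ref_end": 2,
            "tgt_chrom": 3, "tgt_start": 4, "tgt_end": 5,
            "orientation": 6,
        },
    ),
    "satsuma": TableDialect(
        "satsuma",
        {
            "tgt_chrom": 0, "tgt_start": 1, "tgt_end": 2,
            "ref_chrom": 3, "ref_start": 4, "ref_end": 5,
            "score": 6, "orientation": 7,
        },
    ),
    "cinteny": TableDialect(
        "cinteny",
        {
            "block_id": 0,
            "ref_chrom": 1, "ref_start": 2, "ref_end": 3,
            "tgt_chrom": 4, "tgt_start": 5, "tgt_end": 6,
            "orientation": 7,
        },
        coords="1-inclusive",
    ),
    "syntenytracker": TableDialect(
        "syntenytracker",
        {
            "ref_chrom": 0, "ref_start": 1, "ref_end": 2,
            "tgt_chrom": 3, "tgt_start": 4, "tgt_end": 5,
            "block_id": 6, "orientation": 7,
        },
        coords="1-inclusive",
    ),
}


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_chrom_sizes(path: str | Path, genome_name: str | None = None) -> Karyotype:
    """Read a two-column ``chrom.sizes`` file into a Karyotype (file order
    is kept and becomes the plotting/sorting order)."""
    if genome_name is None:
        genome_name = Path(path).stem.split(".")[0]
    chroms: list[tuple[str, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise SyntenyError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        name, length_tok = fields
        try:
            length = int(length_tok)
        except ValueError:
            raise SyntenyError(f"{path}:{lineno}: non-integer length {length_tok!r}") from None
        chroms.append((name, length))
    if not chroms:
        raise SyntenyError(f"{path}: empty chrom.sizes file")
    return Karyotype(genome_name, chroms)


_CHAIN_HEADER_FIELDS = 13  # "chain" + 12 values


def read_chain(path: str | Path, tgt_karyotype: Karyotype | None = None) -> list[Anchor]:
    """Parse a UCSC chain file into one Anchor per ungapped block.

    The chain's t-side is taken as the reference and the q-side as the
    target. ``tStrand`` must be ``+``. When ``qStrand`` is ``-`` the query
    coordinates, which the format expresses on the reversed sequence, are
    converted to forward-strand coordinates (``fwd_start = qSize - rev_end``)
    and the anchor orientation is set to ``-``. Every anchor carries its
    chain's score.
    """
    anchors: list[Anchor] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise SyntenyError(f"{path}: expected chain header, got {line!r}")
        fields = line.split()
        if len(fields) != _CHAIN_HEADER_FIELDS:
            raise SyntenyError(f"{path}: malformed chain header {line!r}")
        (_, score_tok, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, _chain_id) = fields
        try:
            score = float(score_tok)
            t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
            q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        except ValueError:
            raise SyntenyError(f"{path}: non-numeric field in chain header {line!r}") from None
        if t_strand != "+":
            raise SyntenyError(f"{path}: tStrand must be +, got {t_strand!r}")
        if q_strand not in "+-":
            raise SyntenyError(f"{path}: bad qStrand {q_strand!r}")
        if tgt_karyotype is not None:
            if q_name not in tgt_karyotype:
                raise SyntenyError(f"{path}: chain query {q_name!r} not in target karyotype")
            if tgt_karyotype.length_of(q_name) != q_size:
                raise SyntenyError(
                    f"{path}: qSize {q_size} for {q_name} disagrees with karyotype "
                    f"length {tgt_karyotype.length_of(q_name)}"
                )
        t_pos, q_pos = t_start, q_start
        last_block = False
        while i < n:
            data = lines[i].strip()
            i += 1
            if not data:
                break
            if data.startswith("chain"):
                i -= 1
                break
            parts = data.split()
            if len(parts) == 1:
                size, dt, dq = int(parts[0]), 0, 0
                last_block = True
            elif len(parts) == 3:
                size, dt, dq = (int(p) for p in parts)
            else:
                raise SyntenyError(f"{path}: malformed chain data line {data!r}")
            t_block = Interval(t_name, t_pos, t_pos + size)
            if q_strand == "+":
                q_block = Interval(q_name, q_pos, q_pos + size)
            else:
                # q coords are on the reversed strand; flip to forward.
                q_block = Interval(q_name, q_size - (q_pos + size), q_size - q_pos)
            t_pos += size + dt
            q_pos += size + dq
            if t_pos - dt > t_end or q_pos - dq > q_end:
                raise SyntenyError(
                    f"{path}: chain data lines run past declared extent "
                    f"(t {t_pos - dt} > {t_end} or q {q_pos - dq} > {q_end})"
                )
            anchors.append(Anchor(t_block, q_block, q_strand, score))
            if last_block:
                break
    return anchors


def _dialect_of(dialect: TableDialect | str) -> TableDialect:
    if isinstance(dialect, TableDialect):
        return dialect
    try:
        return DIALECT_PRESETS[dialect]
    except KeyError:
        raise SyntenyError(
            f"unknown dialect {dialect!r}; presets: {', '.join(sorted(DIALECT_PRESETS))}"
        ) from None


def read_anchors_tsv(path: str | Path, dialect: TableDialect | str = "generic") -> list[Anchor]:
    """Read anchors from a whitespace-separated table per the dialect,
    normalizing coordinates and orientation tokens."""
    d = _dialect_of(dialect)
    cm = d.column_map
    anchors: list[Anchor] = []
    for lineno, line in _data_lines(path):
        f = line.split()
        try:
            ref = d.interval(f[cm["ref_chrom"]], f[cm["ref_start"]], f[cm["ref_end"]])
            tgt = d.interval(f[cm["tgt_chrom"]], f[cm["tgt_start"]], f[cm["tgt_end"]])
            orient = d.strand(f[cm["orientation"]])
            score = float(f[cm["score"]]) if "score" in cm and cm["score"] < len(f) else 0.0
        except IndexError:
            raise SyntenyError(f"{path}:{lineno}: too few columns for dialect {d.name!r}") from None
        anchors.append(Anchor(ref, tgt, orient, score))
    return anchors


def write_anchors_tsv(anchors: Sequence[Anchor], path: str | Path) -> None:
    """Write anchors in the generic dialect (0-based half-open, strand last)."""
    with open(path, "w") as fh:
        fh.write("# ref_chrom ref_start ref_end tgt_chrom tgt_start tgt_end strand score\n")
        for a in anchors:
            fh.write(
                f"{a.ref.chrom}\t{a.ref.start}\t{a.ref.end}\t"
                f"{a.tgt.chrom}\t{a.tgt.start}\t{a.tgt.end}\t{a.orientation}\t{a.score:g}\n"
            )


_PLACEMENT_RE = re.compile(r"^([^.\s]+)\.(\S+):(\d+)-(\d+)\s+([+-])$")


def write_unified(smap: SyntenyMap, path: str | Path) -> None:
    """Write a map in the unified synteny block definition format (bit-exact;
    see the module docstring for the layout)."""
    with open(path, "w") as fh:
        fh.write(_unified_text(smap))


def _unified_text(smap: SyntenyMap) -> str:
    if "." in smap.reference or any("." in t for t in smap.targets):
        raise SyntenyError("genome names must not contain dots in the unified format")
    out: list[str] = []
    for b in smap.blocks:
        chrom, start, end = to_file_coords(b.ref)
        out.append(f">{b.block_id}\n{smap.reference}.{chrom}:{start}-{end} +\n")
        for tgt_genome in smap.targets:
            if tgt_genome not in b.placements:
                continue
            p = b.placements[tgt_genome]
            c, s, e = to_file_coords(p.tgt)
            out.append(f"{tgt_genome}.{c}:{s}-{e} {p.orientation}\n")
        out.append("\n")
    return "".join(out)


def read_unified(path: str | Path) -> SyntenyMap:
    """Read a unified synteny block definition file; exact inverse of
    :func:`write_unified`."""
    records: list[tuple[int, list[tuple[str, Interval, str]]]] = []
    current: list[tuple[str, Interval, str]] | None = None
    current_id: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    records.append((current_id, current))
                try:
                    current_id = int(line[1:])
                except ValueError:
                    raise SyntenyError(f"{path}:{lineno}: bad block header {line!r}") from None
                current = []
                continue
            if current is None:
                raise SyntenyError(f"{path}:{lineno}: placement line before any '>' header")
            m = _PLACEMENT_RE.match(line)
            if not m:
                raise SyntenyError(f"{path}:{lineno}: unparseable placement line {line!r}")
            genome, chrom, start, end, strand = m.groups()
            current.append((genome, from_file_coords(chrom, int(start), int(end)), strand))
    if current is not None:
        records.append((current_id, current))

    reference: str | None = None
    targets: list[str] = []
    blocks: list[SyntenyBlock] = []
    seen_ids: set[int] = set()
    for block_id, placements in records:
        if block_id in seen_ids:
            raise SyntenyError(f"{path}: duplicate block_id {block_id}")
        seen_ids.add(block_id)
        if len(placements) < 2:
            raise SyntenyError(f"{path}: block {block_id} has no target placement")
        ref_genome, ref_iv, ref_strand = placements[0]
        if ref_strand != "+":
            raise SyntenyError(f"{path}: block {block_id}: reference strand must be +")
        if reference is None:
            reference = ref_genome
        elif ref_genome != reference:
            raise SyntenyError(
                f"{path}: block {block_id} declares reference {ref_genome!r}, expected {reference!r}"
            )
        pl: dict[str, Placement] = {}
        for genome, iv, strand in placements[1:]:
            if genome in pl:
                raise SyntenyError(f"{path}: block {block_id}: duplicate target genome {genome!r}")
            pl[genome] = Placement(iv, strand)
            if genome not in targets:
                targets.append(genome)
        blocks.append(SyntenyBlock(block_id, ref_iv, pl))
    if reference is None:
        return SyntenyMap(reference="", targets=[], blocks=[], resolution=0)
    return SyntenyMap(reference=reference, targets=targets, blocks=blocks, resolution=0)


def convert_third_party(
    path: str | Path,
    dialect: TableDialect | str,
    reference: str,
    target: str,
    ref_karyotype: Karyotype | None = None,
) -> SyntenyMap:
    """Convert a third-party synteny block table to a unified SyntenyMap.

    Rows sharing a ``block_id`` (when the dialect maps one) are merged to
    the enclosing span per genome with majority orientation; without a
    block_id column each row is its own block. The result has resolution 0
    (imported) and blocks renumbered in reference-sorted order.
    """
    d = _dialect_of(dialect)
    cm = d.column_map
    rows: list[tuple[object, Interval, Interval, str]] = []
    for lineno, line in _data_lines(path):
        f = line.split()
        try:
            ref = d.interval(f[cm["ref_chrom"]], f[cm["ref_start"]], f[cm["ref_end"]])
            tgt = d.interval(f[cm["tgt_chrom"]], f[cm["tgt_start"]], f[cm["tgt_end"]])
            orient = d.strand(f[cm["orientation"]])
            bid = f[cm["block_id"]] if "block_id" in cm else None
        except IndexError:
            raise SyntenyError(f"{path}:{lineno}: too few columns for dialect {d.name!r}") from None
        rows.append((bid, ref, tgt, orient))

    grouped: dict[object, list[tuple[Interval, Interval, str]]] = defaultdict(list)
    for i, (bid, ref, tgt, orient) in enumerate(rows):
        key = bid if bid is not None else ("__row__", i)
        grouped[key].append((ref, tgt, orient))

    blocks: list[SyntenyBlock] = []
    for key, members in grouped.items():
        ref_chroms = {r.chrom for r, _, _ in members}
        tgt_chroms = {t.chrom for _, t, _ in members}
        if len(ref_chroms) > 1 or len(tgt_chroms) > 1:
            raise SyntenyError(
                f"{path}: rows of block {key!r} fall on different chromosomes"
            )
        ref_iv = Interval(
            next(iter(ref_chroms)),
            min(r.start for r, _, _ in members),
            max(r.end for r, _, _ in members),
        )
        tgt_iv = Interval(
            next(iter(tgt_chroms)),
            min(t.start for _, t, _ in members),
            max(t.end for _, t, _ in members),
        )
        counts = Counter(o for _, _, o in members)
        # majority orientation; ties resolve to +
        orient = "+" if counts["+"] >= counts["-"] else "-"
        blocks.append(SyntenyBlock(1, ref_iv, {target: Placement(tgt_iv, orient)}))

    smap = SyntenyMap(reference=reference, targets=[target], blocks=blocks, resolution=0)
    smap.sort_blocks(ref_karyotype)
    smap.renumber()
    for prev, cur in zip(smap.blocks, smap.blocks[1:]):
        if cur.ref.chrom == prev.ref.chrom and overlap_len(cur.ref, prev.ref) > 0:
            raise SyntenyError(
                f"{path}: merged blocks overlap on reference: {prev.ref} and {cur.ref}"
            )
    return smap


def read_bed_genes(path: str | Path) -> list[Gene]:
    """Read BED6 gene annotations (chrom, start, end, name, score, strand);
    the score column is ignored but must be present, and the strand must be
    + or - because it drives track colors."""
    genes: list[Gene] = []
    for lineno, line in _data_lines(path):
        f = line.split()
        if len(f) < 6:
            raise SyntenyError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(f)}")
        chrom, start, end, name, _score, strand = f[:6]
        if strand not in "+-":
            raise SyntenyError(f"{path}:{lineno}: gene strand must be + or -, got {strand!r}")
        genes.append(Gene(Interval(chrom, int(start), int(end)), name, strand))
    return genes


def write_bed_genes(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.location.chrom}\t{g.location.start}\t{g.location.end}\t"
                f"{g.name}\t0\t{g.strand}\n"
            )


def read_cytoband(path: str | Path) -> list[Cytoband]:
    """Read a UCSC cytoBandIdeo table (chrom, start, end, band, stain) and
    verify bands on one chromosome do not overlap."""
    bands: list[Cytoband] = []
    for lineno, line in _data_lines(path):
        f = line.split()
        if len(f) < 5:
            raise SyntenyError(f"{path}:{lineno}: cytoband rows need 5 columns")
        chrom, start, end, band, stain = f[:5]
        bands.append(Cytoband(Interval(chrom, int(start), int(end)), band, stain))
    by_chrom: dict[str, list[Cytoband]] = defaultdict(list)
    for b in bands:
        by_chrom[b.location.chrom].append(b)
    for chrom, bs in by_chrom.items():
        bs_sorted = sorted(bs, key=lambda b: b.location.start)
        for prev, cur in zip(bs_sorted, bs_sorted[1:]):
            if overlap_len(prev.location, cur.location) > 0:
                raise SyntenyError(
                    f"{path}: overlapping cytobands on {chrom}: "
                    f"{prev.band_name} and {cur.band_name}"
                )
    return bands
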