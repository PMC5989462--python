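"""Block-based rearrangement and gene analyses.

Given a synteny map these operations answer the questions a comparative
genomicist asks of it: which target chromosomes does each reference
chromosome connect to (translocation / fission / fusion signature), how
shuffled is the block order within one partner chromosome (inversion /
transposition signature), which genes sit wholly inside a conserved block,
which fall in uncovered sequence, and which are broken — overlap two or
more blocks, placing a rearrangement breakpoint inside the gene.

Order-breaking is quantified per partner chromosome as the number of blocks
outside one maximal collinear arrangement: the longest strictly increasing
subsequence of target midpoints over forward blocks, or the longest
strictly decreasing subsequence over inverted blocks, whichever is longer.
A perfectly collinear chromosome scores 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import Gene, Karyotype, SyntenyError, SyntenyMap, overlap_len

__all__ = [
    "ChromosomeReport",
    "GeneClass",
    "connectivity",
    "classify_chromosome",
    "classify_genes",
    "coverage_summary",
    "write_chromosome_report_tsv",
    "write_gene_report_tsv",
    "write_coverage_tsv",
]


@dataclass(frozen=True)
class ChromosomeReport:
    """Rearrangement classification of one reference chromosome against one
    target genome."""

    ref_chrom: str
    target: str
    partner_chroms: frozenset[str]
    n_blocks: int
    n_inverted: int
    n_order_breaking: int
    rearrangement_class: str  # collinear | intra_only | inter

    def __post_init__(self) -> None:
        if self.rearrangement_class not in ("collinear", "intra_only", "inter", "empty"):
            raise SyntenyError(f"bad class {self.rearrangement_class!r}")


@dataclass(frozen=True)
class GeneClass:
    """One gene's relationship to the blocks of a pairwise projection."""

    gene: Gene
    gene_class: str  # conserved | unplaced | broken
    n_blocks: int
    partial: bool = False  # conserved gene that sticks out of its single block


def connectivity(
    smap: SyntenyMap,
    ref_chrom: str,
    target: str,
    ref_karyotype: Karyotype | None = None,
) -> set[str]:
    """The distinct target chromosomes receiving at least one block from
    ``ref_chrom`` (empty set for a blockless chromosome). When a reference
    karyotype is given, an unknown chromosome name is an error."""
    blocks = smap.blocks_for(target)
    if ref_karyotype is not None and ref_chrom not in ref_karyotype:
        raise SyntenyError(f"unknown reference chromosome {ref_chrom!r}")
    return {
        b.placements[target].tgt.chrom for b in blocks if b.ref.chrom == ref_chrom
    }


def _longest_monotone(values: Sequence[float], decreasing: bool = False) -> int:
    """Length of the longest strictly increasing (or decreasing)
    subsequence, O(n log n) patience sorting."""
    if decreasing:
        values = [-v for v in values]
    tails: list[float] = []
    for v in values:
        i = bisect.bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def classify_chromosome(smap: SyntenyMap, ref_chrom: str, target: str) -> ChromosomeReport:
    """Classify one reference chromosome against one target genome.

    ``inter`` — blocks land on two or more target chromosomes;
    ``intra_only`` — a single partner chromosome but inversions or order
    changes among its blocks; ``collinear`` — a single partner chromosome,
    no inversions, blocks in one collinear order; ``empty`` — no blocks.
    """
    blocks = [b for b in smap.blocks_for(target) if b.ref.chrom == ref_chrom]
    partners = {b.placements[target].tgt.chrom for b in blocks}
    n_inverted = sum(1 for b in blocks if b.placements[target].orientation == "-")

    n_order_breaking = 0
    for chrom in sorted(partners):
        members = [b for b in blocks if b.placements[target].tgt.chrom == chrom]
        mids = [
            (b.placements[target].tgt.start + b.placements[target].tgt.end) / 2
            for b in members
        ]
        fwd = [m for b, m in zip(members, mids) if b.placements[target].orientation == "+"]
        rev = [m for b, m in zip(members, mids) if b.placements[target].orientation == "-"]
        best = max(_longest_monotone(fwd), _longest_monotone(rev, decreasing=True))
        n_order_breaking += len(members) - best

    if not blocks:
        cls = "empty"
    elif len(partners) >= 2:
        cls = "inter"
    elif n_inverted == 0 and n_order_breaking == 0:
        cls = "collinear"
    else:
        cls = "intra_only"
    return ChromosomeReport(
        ref_chrom=ref_chrom,
        target=target,
        partner_chroms=frozenset(partners),
        n_blocks=len(blocks),
        n_inverted=n_inverted,
        n_order_breaking=n_order_breaking,
        rearrangement_class=cls,
    )


def classify_genes(genes: Iterable[Gene], smap: SyntenyMap, target: str) -> list[GeneClass]:
    """Classify reference genes against the pairwise projection of the map
    onto one target: conserved (inside exactly one block), broken (overlaps
    two or more blocks), unplaced (no overlap). A gene overlapping a single
    block only partially is conserved with ``partial=True``."""
    blocks = smap.blocks_for(target)
    trees: dict[str, IntervalTree] = {}
    for b in blocks:
        trees.setdefault(b.ref.chrom, IntervalTree()).addi(b.ref.start, b.ref.end, b)
    out: list[GeneClass] = []
    for gene in genes:
        tree = trees.get(gene.location.chrom)
        hits = sorted(tree.overlap(gene.location.start, gene.location.end)) if tree else []
        n = len(hits)
        if n == 0:
            out.append(GeneClass(gene, "unplaced", 0))
        elif n == 1:
            block = hits[0].data
            inside = block.ref.contains(gene.location)
            out.append(GeneClass(gene, "conserved", 1, partial=not inside))
        else:
            out.append(GeneClass(gene, "broken", n))
    return out


def coverage_summary(smap: SyntenyMap, karyotype: Karyotype) -> dict:
    """Per-chromosome and genome-wide reference bp covered by blocks and the
    covered fraction. Block reference intervals are disjoint by invariant,
    so covered bp is the plain sum of spans."""
    per_chrom: dict[str, dict[str, float]] = {}
    for name, length in karyotype.chromosomes:
        per_chrom[name] = {"length": length, "covered_bp": 0, "fraction": 0.0}
    for b in smap.blocks:
        if b.ref.chrom not in per_chrom:
            raise SyntenyError(f"block chromosome {b.ref.chrom!r} absent from karyotype")
        per_chrom[b.ref.chrom]["covered_bp"] += b.ref.length
    for name in per_chrom:
        entry = per_chrom[name]
        entry["fraction"] = entry["covered_bp"] / entry["length"]
    total_len = karyotype.total_length
    total_cov = sum(e["covered_bp"] for e in per_chrom.values())
    return {
        "per_chrom": per_chrom,
        "genome": {
            "length": total_len,
            "covered_bp": total_cov,
            "fraction": total_cov / total_len if total_len else 0.0,
        },
    }


# ---------------------------------------------------------------------------
# TSV serialization (fixed, documented column orders)


def write_chromosome_report_tsv(reports: Sequence[ChromosomeReport], path) -> None:
    """Columns: ref_chrom, target, class, n_blocks, n_inverted,
    n_order_breaking, partner_chroms (comma-joined, sorted)."""
    with open(path, "w") as fh:
        fh.write("ref_chrom\ttarget\tclass\tn_blocks\tn_inverted\tn_order_breaking\tpartner_chroms\n")
        for r in reports:
            fh.write(
                f"{r.ref_chrom}\t{r.target}\t{r.rearrangement_class}\t{r.n_blocks}\t"
                f"{r.n_inverted}\t{r.n_order_breaking}\t{','.join(sorted(r.partner_chroms))}\n"
            )


def write_gene_report_tsv(gene_classes: Sequence[GeneClass], target: str, path) -> None:
    """Columns: gene, chrom, start (0-based), end, strand, target, class,
    n_blocks, partial (0/1)."""
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\tstrand\ttarget\tclass\tn_blocks\tpartial\n")
        for gc in gene_classes:
            g = gc.gene
            fh.write(
                f"{g.name}\t{g.location.chrom}\t{g.location.start}\t{g.location.end}\t"
                f"{g.strand}\t{target}\t{gc.gene_class}\t{gc.n_blocks}\t{int(gc.partial)}\n"
            )


def write_coverage_tsv(summary: dict, path) -> None:
    """Columns: chrom (or GENOME total row), length, covered_bp, fraction."""
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tcovered_bp\tfraction\n")
        for name, e in summary["per_chrom"].items():
            fh.write(f"{name}\t{e['length']}\t{e['covered_bp']}\t{e['fraction']:.6f}\n")
        g = summary["genome"]
        fh.write(f"GENOME\t{g['length']}\t{g['covered_bp']}\t{g['fraction']:.6f}\n")
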