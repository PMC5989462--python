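"""Connectivity, rearrangement classification, gene classes and coverage."""

import itertools

import numpy as np
import pytest

from syntenykit.core import Gene, Interval, Karyotype, Placement, SyntenyBlock, SyntenyError, SyntenyMap
from syntenykit.analysis import (
    _longest_monotone,
    classify_chromosome,
    classify_genes,
    connectivity,
    coverage_summary,
    write_chromosome_report_tsv,
    write_coverage_tsv,
    write_gene_report_tsv,
)
from syntenykit.simulate import genes_from_truth, mask_blocks, simulate_karyotype, simulate_rearrangements


def make_map(placements, ref_spans=None, target="mm"):
    """placements: list of (tgt_chrom, tgt_start, tgt_end, orient)."""
    blocks = []
    pos = 0
    for i, (tc, ts, te, o) in enumerate(placements, start=1):
        span = (te - ts)
        ref = Interval("chr2", pos, pos + span) if ref_spans is None else Interval("chr2", *ref_spans[i - 1])
        pos += span + 10
        blocks.append(SyntenyBlock(i, ref, {target: Placement(Interval(tc, ts, te), o)}))
    return SyntenyMap("hg", [target], blocks)


# --------------------------------------------------------------- connectivity

def test_connectivity_distinct_partner_set():
    m = make_map([("mA", 0, 100, "+"), ("mB", 0, 100, "+"), ("mA", 200, 300, "+")])
    assert connectivity(m, "chr2", "mm") == {"mA", "mB"}


def test_connectivity_empty_for_blockless_chromosome():
    m = make_map([("mA", 0, 100, "+")])
    k = Karyotype("hg", [("chr2", 10_000), ("chr3", 10_000)])
    assert connectivity(m, "chr3", "mm", k) == set()
    with pytest.raises(SyntenyError):
        connectivity(m, "chrNope", "mm", k)
    with pytest.raises(KeyError):
        connectivity(m, "chr2", "not-a-target")


def test_connectivity_recovers_planted_translocation_partners():
    from syntenykit.simulate import RearrangementOp
    k = simulate_karyotype(3, (1_000_000, 1_000_000), seed=3)
    ops = [
        RearrangementOp("translocation", (0, 400_000, 1, 500_000)),
        RearrangementOp("translocation", (0, 200_000, 2, 300_000)),
    ]
    ts = simulate_rearrangements(k, ops=ops)
    # chr1 was cut twice and swapped with chr2 and chr3: three partners
    assert connectivity(ts.truth_map, "chr1", "tgt") == {"chr1", "chr2", "chr3"}


# ------------------------------------------------------------- classification

def test_collinear_chromosome():
    m = make_map([("mA", 0, 100, "+"), ("mA", 150, 260, "+"), ("mA", 300, 420, "+")])
    r = classify_chromosome(m, "chr2", "mm")
    assert r.rearrangement_class == "collinear"
    assert r.n_order_breaking == 0 and r.n_inverted == 0


def test_single_inversion_is_intra_only():
    m = make_map([("mA", 0, 100, "+"), ("mA", 150, 260, "-"), ("mA", 300, 420, "+")])
    r = classify_chromosome(m, "chr2", "mm")
    assert r.rearrangement_class == "intra_only"
    assert r.n_inverted == 1


def test_two_partners_is_inter_regardless_of_order():
    m = make_map([("mA", 0, 100, "+"), ("mB", 0, 100, "+")])
    assert classify_chromosome(m, "chr2", "mm").rearrangement_class == "inter"


def test_order_breaking_counts_blocks_outside_collinear_order():
    # forward blocks in target order 1,3,2: one block breaks the order
    m = make_map([("mA", 0, 100, "+"), ("mA", 300, 400, "+"), ("mA", 150, 250, "+")])
    r = classify_chromosome(m, "chr2", "mm")
    assert r.n_order_breaking == 1
    assert r.rearrangement_class == "intra_only"


def lis_oracle(values, decreasing=False):
    """Exhaustive longest strictly monotone subsequence for small inputs."""
    best = 0
    for r in range(len(values), 0, -1):
        for combo in itertools.combinations(values, r):
            ok = all(b < a for a, b in zip(combo, combo[1:])) if decreasing \
                else all(a < b for a, b in zip(combo, combo[1:]))
            if ok:
                return r
    return best


@pytest.mark.parametrize("seed", range(20))
def test_longest_monotone_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 20, size=int(rng.integers(1, 11))).tolist()
    assert _longest_monotone(vals) == lis_oracle(vals)
    assert _longest_monotone(vals, decreasing=True) == lis_oracle(vals, decreasing=True)


def test_no_order_breaking_without_intra_ops():
    k = simulate_karyotype(4, (900_000, 1_100_000), seed=5)
    ts = simulate_rearrangements(k, ops=[])
    for chrom in k.names:
        r = classify_chromosome(ts.truth_map, chrom, "tgt")
        assert r.rearrangement_class == "collinear"
        assert r.n_order_breaking == 0


def test_connectivity_equals_report_partner_set():
    m = make_map([("mA", 0, 100, "+"), ("mB", 0, 100, "-"), ("mA", 200, 300, "+")])
    r = classify_chromosome(m, "chr2", "mm")
    assert set(r.partner_chroms) == connectivity(m, "chr2", "mm")


# --------------------------------------------------------------- gene classes

def gene(s, e, name="G", strand="+", chrom="chr2"):
    return Gene(Interval(chrom, s, e), name, strand)


def test_gene_inside_one_block_is_conserved():
    m = make_map([("mA", 0, 450, "+")], ref_spans=[(50, 500)])
    (gc,) = classify_genes([gene(100, 200)], m, "mm")
    assert gc.gene_class == "conserved" and gc.n_blocks == 1 and not gc.partial


def test_gene_over_two_blocks_is_broken():
    m = make_map([("mA", 0, 150, "+"), ("mA", 150, 400, "+")],
                 ref_spans=[(0, 150), (150, 400)])
    (gc,) = classify_genes([gene(100, 200)], m, "mm")
    assert gc.gene_class == "broken" and gc.n_blocks == 2


def test_gene_without_overlap_is_unplaced():
    m = make_map([("mA", 0, 100, "+")], ref_spans=[(0, 100)])
    (gc,) = classify_genes([gene(600, 700)], m, "mm")
    assert gc.gene_class == "unplaced" and gc.n_blocks == 0


def test_partially_overhanging_gene_is_conserved_with_partial_flag():
    m = make_map([("mA", 0, 100, "+")], ref_spans=[(0, 100)])
    (gc,) = classify_genes([gene(50, 150)], m, "mm")
    assert gc.gene_class == "conserved" and gc.partial


def test_classes_partition_gene_set():
    m = make_map([("mA", 0, 150, "+"), ("mA", 150, 400, "+")],
                 ref_spans=[(0, 150), (150, 400)])
    genes = [gene(10, 50), gene(140, 160), gene(900, 950)]
    out = classify_genes(genes, m, "mm")
    assert len(out) == len(genes)
    counts = {c: sum(1 for g in out if g.gene_class == c)
              for c in ("conserved", "broken", "unplaced")}
    assert sum(counts.values()) == len(genes)


def test_planted_gene_classes_fully_recovered():
    """Confusion matrix between intended and computed classes is diagonal,
    and the planted three-block spanner overlaps exactly 3 blocks."""
    k = simulate_karyotype(5, (1_600_000, 2_400_000), seed=7)
    ts = simulate_rearrangements(k, n_ops=20, seed=7)
    masked = mask_blocks(ts.truth_map, 0.15, seed=7)
    planted = genes_from_truth(masked, n_per_class=8, seed=7, ref_karyotype=k)
    out = classify_genes([g for g, _ in planted], masked, "tgt")
    for (g, intended), computed in zip(planted, out):
        assert computed.gene_class == intended, g.name
    spanners = [c for c in out if c.gene.name.endswith("SPAN3")]
    assert spanners and spanners[0].n_blocks == 3


# ------------------------------------------------------------------- coverage

def test_coverage_fraction_arithmetic():
    k = Karyotype("hg", [("chr2", 1000)])
    m = make_map([("mA", 0, 500, "+")], ref_spans=[(0, 500)])
    s = coverage_summary(m, k)
    assert s["per_chrom"]["chr2"]["covered_bp"] == 500
    assert s["genome"]["fraction"] == 0.5
    m2 = make_map([("mA", 0, 300, "+"), ("mA", 400, 600, "+")],
                  ref_spans=[(0, 300), (500, 700)])
    assert coverage_summary(m2, k)["genome"]["covered_bp"] == 500


def test_coverage_of_empty_map_is_zero():
    k = Karyotype("hg", [("chr2", 1000)])
    s = coverage_summary(SyntenyMap("hg", ["mm"], []), k)
    assert s["genome"]["covered_bp"] == 0 and s["genome"]["fraction"] == 0


def test_coverage_unknown_chromosome_rejected():
    k = Karyotype("hg", [("chrZ", 1000)])
    m = make_map([("mA", 0, 100, "+")], ref_spans=[(0, 100)])
    with pytest.raises(SyntenyError):
        coverage_summary(m, k)


# ------------------------------------------------------------------- reports

def test_report_tsv_round(tmp_path):
    m = make_map([("mA", 0, 100, "+"), ("mB", 0, 100, "-")])
    r = classify_chromosome(m, "chr2", "mm")
    p = tmp_path / "chrom.tsv"
    write_chromosome_report_tsv([r], p)
    header, row = p.read_text().splitlines()
    assert header.split("\t")[:3] == ["ref_chrom", "target", "class"]
    assert row.split("\t")[2] == "inter"

    gc = classify_genes([gene(10, 50)], m, "mm")
    p = tmp_path / "genes.tsv"
    write_gene_report_tsv(gc, "mm", p)
    assert len(p.read_text().splitlines()) == 2

    k = Karyotype("hg", [("chr2", 100000)])
    p = tmp_path / "cov.tsv"
    write_coverage_tsv(coverage_summary(m, k), p)
    assert p.read_text().splitlines()[-1].startswith("GENOME\t")
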