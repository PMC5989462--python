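# syntenykit

Desk-scale synteny block construction, rearrangement analysis and
comparative-genomics visualization.

Synteny blocks — genomic segments whose sequence order is conserved between
species — are the basic unit of large-scale comparative genomics: they
reveal which chromosomes exchanged material, where inversions shuffled gene
order, and which genes sit on rearrangement breakpoints. Building them
normally involves whole-genome alignment pipelines and a web stack;
`syntenykit` covers everything downstream of alignment as a plain Python
library and CLI for people who already have pairwise alignment anchors
(UCSC chain files or tab-separated match tables) or block definitions from
other tools (Satsuma, Cinteny, SyntenyTracker-style tables).

## What it does

* **Block construction.** Anchors are filtered (`min_anchor`), chained
  greedily along the reference into maximal collinear runs — same target
  chromosome, same orientation, gaps on both genomes within
  `[-min_anchor, max_gap]`, target coordinates advancing with (for `+`) or
  against (for `-`) the reference — and each run becomes a block spanning
  its anchors. Blocks shorter than the **resolution** on either genome are
  dropped, residual overlaps are resolved deterministically, and pairwise
  maps are intersected into multi-species blocks conserved across *every*
  target.
* **Unified format.** All maps are stored in one diffable text format
  (`>id`, then one `genome.chrom:start-end strand` line per placement,
  1-based inclusive), with converters from third-party block tables driven
  by editable column-map dialects.
* **Analysis.** Per reference chromosome: partner-chromosome connectivity,
  inversion counts, blocks outside the longest collinear order, and an
  inter / intra-only / collinear classification. Per gene: conserved
  (inside one block), broken (spanning ≥ 2 blocks — a breakpoint inside
  the gene), or unplaced (uncovered sequence).
* **Visualization.** Deterministic SVG: a circular whole-genome plot (one
  ribbon per block placement, optional cytoband ring, chromosome
  highlighting) and per-chromosome linear plots (bow-tie quadrilaterals
  for inverted blocks, strand-colored gene track, red marker for a
  highlighted gene), plus a static HTML site with one browser page per
  (reference chromosome × target).
* **Simulation.** A rearrangement simulator (inversions, reciprocal
  translocations, fissions, fusions, transpositions) that produces exact
  ground-truth block decompositions, noisy anchors and genes with known
  classes — so the whole pipeline is testable without downloading genomes.

## Worked example

Simulate a five-chromosome ~11 Mb genome, rearrange it 20 times, and
rebuild the blocks from the emitted anchors:

```bash
$ syntenykit simulate --out demo --seed 7 --n-chroms 5 \
      --chrom-length 2000000 --n-ops 20 --resolution 50000
wrote fixture with 32 truth blocks, 452 anchors, 15 genes to demo
$ syntenykit build demo/config.ini
built demo/build
$ syntenykit analyze demo/build --target tgt
wrote demo/build/chromosomes_tgt.tsv
wrote demo/build/coverage_tgt.tsv
wrote demo/build/genes_tgt.tsv
```

`chromosomes_tgt.tsv` classifies each reference chromosome against the
rearranged genome:

```
ref_chrom  target  class       n_blocks  n_inverted  n_order_breaking  partner_chroms
chr1       tgt     inter       10        6           4                 chr1,chr2
chr2       tgt     intra_only  8         5           5                 chr1
chr3       tgt     inter       3         0           1                 chr1,chr2
```

`chr1` sends blocks to two target chromosomes (`inter`: a translocation /
fission / fusion signature); `chr2` keeps a single partner but has 5
inverted and 5 order-breaking blocks (`intra_only`). The gene report pins
individual genes to blocks — here the planted three-block spanner and an
unplaced gene:

```
BROK1_SPAN3  chr1  1194634  1589076  -  tgt  broken    3  0
UNPL1        chr5  246339   246839   +  tgt  unplaced  0  0
```

A `broken` gene with `n_blocks = 3` straddles two rearrangement
breakpoints — the geometry that marks a gene disrupted (or newly arisen)
since the species split. Plots and a browsable site come from the same
build directory:

```bash
$ syntenykit plot demo/build --ref-chrom chr1 --target tgt
wrote demo/build/plots/circos.svg
wrote demo/build/plots/linear_chr1_tgt.svg
$ syntenykit site demo/build
wrote 7 pages under demo/build/site
```

Third-party block tables convert to the unified format with
`syntenykit convert table.tsv --dialect satsuma --reference hg
--target mm --out blocks.synteny`. A commented build configuration is in
`examples/config.example.ini`.

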