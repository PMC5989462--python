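# Methods

## Coordinate model

All coordinates are 0-based half-open internally; every file format
declares its own convention at the I/O boundary (chain query coordinates on
the reversed strand are flipped with `fwd_start = qSize - rev_end`; the
unified block format prints 1-based inclusive). A block's reference strand
is always `+`: inversion is a property of a target placement, whose
interval is stored on the target's forward strand with orientation `-`.
Chromosome order is the order of the karyotype file, never lexicographic,
so `chr1..chr22,chrX` survives sorting and plotting untouched.

## Block construction

The construction is the classic conserved-segment recipe over alignment
anchors:

1. **Filter.** Anchors whose shorter side is below `min_anchor` (default
   100 bp) are discarded; survivors are sorted by reference position
   (ties: larger span first).
2. **Chain.** A single left-to-right sweep per reference chromosome grows
   collinear runs. An anchor may extend a run iff it shares the run's
   target chromosome and orientation, its reference gap to the run's last
   anchor lies in `[-min_anchor, max_gap]`, its target gap — measured in
   the orientation's direction of travel — lies in the same band, and the
   target keeps strictly advancing (forward for `+`, backward for `-`).
   Several runs may be open simultaneously: an anchor joins the most
   recently opened compatible run, else opens its own. This is the one
   genuinely open design point; the windowed multi-run sweep was chosen
   because it makes chaining robust to interleaved noise — a lone
   off-diagonal anchor starts a short run that the size filter later
   removes, instead of severing a collinear one. A run closes when the
   sweep passes `max_gap` beyond its reference end, so the sweep stays
   linear in the number of anchors. Small anchor overlaps (as produced by
   chain trimming) are tolerated as negative gaps down to `-min_anchor`.
3. **Blocks.** Each run becomes a candidate block: reference span from
   first anchor start to last anchor end, target span the enclosing span
   of member target intervals, orientation the run's. Blocks below the
   **resolution** on either genome are dropped. Resolution is the single
   user-facing scale knob: it is both the minimum block span and the
   default `max_gap`.
4. **Overlap resolution.** Residual overlaps (possible under noise) are
   resolved by a deterministic sweep: of two overlapping blocks the one
   with the smaller reference span is trimmed by the overlap on the
   overlapping side (the opposite genome's interval is cropped
   linearly, orientation-aware); a block trimmed below the resolution is
   dropped. Reference-side and target-side sweeps alternate to a
   fixpoint. Trimming rather than discarding preserves coverage and keeps
   the outcome independent of input order.
5. **Intersection.** Multi-species blocks require conservation in *all*
   targets: the reference is cut at the union of all pairwise block
   boundaries, and a segment survives iff exactly one block of every
   pairwise map covers it and it spans at least the resolution. Target
   placements are cropped in linear proportion to the reference crop,
   from the far end for inverted placements.

Identical inputs and parameters produce byte-identical unified files; all
tie-breaks (sorting, trimming, orientation majorities) are fixed.

## Rearrangement classification

For one reference chromosome against one target genome:

* `inter` — blocks land on ≥ 2 target chromosomes (translocation /
  fission / fusion signature);
* `intra_only` — one partner chromosome, but inverted blocks or blocks
  out of collinear order;
* `collinear` — one partner chromosome, no inversions, order intact;
* `empty` — no blocks (the three-way scheme is undefined at zero blocks).

"Out of order" is made concrete as: `n_blocks` minus the size of the best
collinear arrangement per partner chromosome, where the best arrangement
is the longer of the longest strictly increasing subsequence of target
midpoints over forward blocks and the longest strictly decreasing
subsequence over inverted blocks. This statistic is 0 exactly when no
intra-chromosomal operation separates the two genomes, is deterministic,
and is verifiable by exhaustive subsequence search for small inputs.

Gene classes against a pairwise projection: **conserved** = overlaps
exactly one block (flagged `partial` when not fully contained),
**broken** = positive overlap with ≥ 2 blocks (a breakpoint inside the
gene), **unplaced** = no overlap. Broken status deliberately requires two
blocks — a gene merely poking out of one block is not evidence of a
breakpoint. A gene may be broken against one target and conserved against
another; reports are always per target.

## Simulator

The simulator evolves a copy of the reference karyotype through
bp-preserving operations (inversion, reciprocal translocation, fission,
fusion, transposition) applied to a segment list. Because no sequence is
gained or lost, the final segments tile the reference exactly and the
induced truth map is exact by construction; segments split by a breakpoint
that a later operation re-joins are merged back, so truth blocks are
maximal. Random operation lists keep every breakpoint at least
`min_segment` (default 100 kb) from existing boundaries, which bounds the
smallest truth block from below and makes "resolution below the smallest
truth block" a checkable precondition for exact recovery.

Anchors tile each truth block with alternating anchor/gap stretches drawn
uniformly within ±50% of the requested means (defaults 20 kb / 2 kb; a
uniform family keeps the harness dependency-free and the draws bounded),
pinned to the block's ends so noise-free anchor extremes equal truth
boundaries. Noise has three independent dials: boundary jitter (clipped
normal, |δ| ≤ 3σ, kept inside the block so anchors never leak across
breakpoints), uniformly placed spurious anchors, and random anchor
drop-out. Genes with intended classes are planted against a (typically
block-masked) truth map; uncovered gaps for unplaced genes come from
masking blocks out of the emitted anchors, never from non-conservative
operations, so truth bookkeeping stays exact.

What the simulator does **not** emulate: nucleotide-level divergence,
repeats and segmental duplications, gene loss/gain, assembly gaps, or
alignment artifacts beyond the three noise dials. Passing tests therefore
demonstrate algorithmic correctness on the stated noise model, not
performance on real mammalian alignments, where anchor quality — not
chaining — usually dominates.

### Evaluation conditions

Recovery experiments use a 5-chromosome, ~10 Mb genome (chromosome lengths
uniform in 1.6–2.4 Mb) through 20 mixed operations, anchors at 20 kb / 2 kb
means, built at resolution 50 kb — sizes at which the full suite and the
acceptance script run in seconds while every code path (all operation
kinds, multi-chromosome sorting, inversion geometry) is exercised. The
noise setting is jitter σ = 1 kb, 5% spurious anchors, 5% drop-out over 20
replicate genomes. Under noise the build uses the default
`max_gap = resolution`: drop-out punches ~24 kb holes in the anchor
tiling, which a 10 kb `max_gap` would (correctly, but uselessly) refuse to
bridge. A truth block counts as recovered when the compatible built blocks
(same target chromosome and orientation, overlapping reference) reach
within `max_gap` of both truth boundaries; a built block is chimeric when
it overlaps truth blocks that disagree in target chromosome or
orientation. Measured: exact block-for-block equality without noise, ~99%
recovery with zero chimeras under noise (`scripts/acceptance.py`
recomputes both).

## Rendering

SVG is the rendering contract: deterministic output (fixed float
precision, fixed palette keyed by chromosome index, no timestamps), stable
class names for counting (`ribbon`, `quad`, `bowtie`, `gene`,
`gene-marker`, `cytoband`, `chrom-arc`, `track`), and geometry that is
exactly proportional — arc sweep to chromosome bp (fixed 2° inter-sector
gap), drawn span width to block span. Interactive behaviors of a live
browser (hover boxes, click-through) are replaced by static equivalents:
per-block coordinates embedded as `<title>` metadata, highlight options
that dim non-incident ribbons, and a static HTML tree with deterministic
file names. PNG/JPEG/PDF are produced only when the optional `cairosvg`
backend is importable; without it the SVG is still always written.

## Numerical and degenerate-input choices

* Proportional cropping of placements rounds to integers, clamps into the
  parent interval, and never emits an empty interval (a collapsed crop
  becomes 1 bp).
* Orientation ties when merging third-party rows resolve to `+`.
* Duplicate anchors are harmless: chaining refuses non-advancing anchors,
  and overlap resolution makes a duplicated anchor list build the same map
  as a single copy.
* Empty inputs degrade cleanly: an empty anchor set builds an empty map,
  an empty map writes an empty unified file (read back as an empty map
  with no genome names), and coverage of an empty map is zero.

## Known limitations

* Chaining is greedy, not score-optimal: a pathological anchor ordering
  could split a run that global dynamic programming would keep. The
  brute-force-verified preference rule keeps this deterministic.
* Overlap trimming assumes approximately linear anchor geometry inside a
  block; under extreme noise the proportional crop can misplace a trimmed
  target boundary by a few bp.
* One reference genome per map; reference-free (all-pairs) synteny and
  ancestral reconstruction are out of scope.
* Imported third-party maps carry resolution 0 and are taken at face
  value apart from invariant checks (no re-chaining).
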