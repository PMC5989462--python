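; Example build configuration for `syntenykit build`.
; Paths are resolved relative to this file's directory.

[reference]
name = hg            ; genome label used in output files (no dots)
sizes = hg.chrom.sizes
genes = hg.genes.bed          ; optional: BED6 gene annotations
cytoband = hg.cytoband.txt    ; optional: UCSC cytoBandIdeo table

; One section per target genome. Each needs exactly one anchor/block
; source: a UCSC chain file, a generic anchor TSV, or a third-party
; synteny block table (converted with the named dialect).
[target:mm]
sizes = mm.chrom.sizes
chain = hg.mm.chain

[target:bt]
sizes = bt.chrom.sizes
anchors = hg.bt.anchors.tsv
dialect = generic             ; preset: generic | satsuma | cinteny | syntenytracker

[params]
resolution = 150000  ; minimum block span (bp) on reference and each target
max_gap = 150000     ; max joinable anchor gap (bp); defaults to resolution
min_anchor = 100     ; discard anchors shorter than this on either genome

[output]
dir = build_hg       ; each config builds its own independent directory
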